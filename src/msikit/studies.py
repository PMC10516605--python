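"""Seeded simulation studies of the caller's operating characteristics.

Each study runs the package end to end on generator output and returns the
measured quantities (calibration, power, classifier accuracy, table
recovery).  They are the basis of the validation suite and of the
reproduction script; problem sizes are chosen so each study runs in
seconds to a few minutes on one core.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import call_positives, fit_all_backgrounds
from .counting import histogram_frame, tabulate
from .msi import score_sample
from .panel import (
    CODING_TARGET_CONFIG,
    MSI_MARKER_CONFIG,
    default_panel,
    make_locus_panel,
)
from .simulate import (
    SampleSpec,
    control_specs,
    null_cohort_specs,
    simulate_marker_traces,
    simulate_repeat_count_histogram,
)
from .background import weibull_mle

CODING_GENES = [c["locus_id"] for c in CODING_TARGET_CONFIG]


def cohort_count_table(panel, specs: Sequence[SampleSpec]) -> pd.DataFrame:
    """Count-level cohort: observed-repeat histograms straight from the
    generator (the read-level model marginalised over substitution errors)."""
    frames = [
        histogram_frame(s.sample_id, loc.locus_id,
                        simulate_repeat_count_histogram(loc, s))
        for s in specs for loc in panel
        if s.depth_for(loc.locus_id) > 0
    ]
    return tabulate(pd.concat(frames, ignore_index=True), panel)


def weibull_recovery_study(
    combos: Sequence[tuple[float, float]] = ((0.8, 0.005), (1.3, 0.01), (2.0, 0.02)),
    n_draws: int = 200,
    n_seeds: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """MLE recovery of known Weibull background parameters."""
    rows = []
    for k_true, lam_true in combos:
        for rep in range(n_seeds):
            rng = np.random.default_rng([seed, int(k_true * 1000), rep])
            x = rng.weibull(k_true, n_draws) * lam_true
            k_hat, lam_hat, converged = weibull_mle(x)
            rows.append(
                {
                    "k_true": k_true, "lam_true": lam_true, "rep": rep,
                    "k_hat": k_hat, "lam_hat": lam_hat, "converged": converged,
                    "k_rel_err": abs(k_hat - k_true) / k_true,
                    "lam_rel_err": abs(lam_hat - lam_true) / lam_true,
                }
            )
    return pd.DataFrame(rows)


def null_cohort_study(
    n_cohorts: int = 100,
    n_controls: int = 8,
    n_tumors: int = 10,
    depth: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Type-I behaviour on all-null cohorts (WT-like tumors, stutter-only
    noise): per-cohort raw p<alpha rejection rate and the false discovery
    proportion of the BH-thresholded calls (all calls are false here)."""
    panel = default_panel(seed=0)
    rows = []
    for c in range(n_cohorts):
        specs = null_cohort_specs(n_controls=n_controls, n_tumors=n_tumors,
                                  depth=depth, base_seed=(seed * 1_000_003 + c * 97) % 2**31)
        groups = {s.sample_id: s.group for s in specs}
        counts = cohort_count_table(panel, specs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = fit_all_backgrounds(counts, groups)
            calls = call_positives(counts, models, groups, alpha=alpha)
        n_rej = int(calls["positive"].sum())
        rows.append(
            {
                "cohort": c,
                "n_tests": len(calls),
                "raw_rejection_rate": float((calls["p_value"] < alpha).mean()),
                "n_bh_calls": n_rej,
                "fdp": 1.0 if n_rej else 0.0,  # every call on a null cohort is false
            }
        )
    return pd.DataFrame(rows)


def power_study(
    vaf: float = 0.3,
    n_seeds: int = 50,
    n_controls: int = 8,
    n_tumors: int = 10,
    depth: int = 2000,
    min_vaf: float = 0.05,
    seed: int = 0,
) -> dict:
    """Recovery of -1 frameshifts planted in every tumor at the five coding
    targets.  Returns detection rate over planted events and precision of
    the target calls (fraction of positive target calls that are planted)."""
    panel = default_panel(seed=0)
    targets = [(g, -1) for g in CODING_GENES]
    n_planted = n_called = n_pos_calls = n_true_calls = 0
    for rep in range(n_seeds):
        base = (seed * 2_000_003 + rep * 1009) % 2**31
        specs = list(control_specs(n_controls, depth, base))
        for i in range(n_tumors):
            specs.append(
                SampleSpec(f"T{i:02d}", "tumor", depth,
                           planted_indels={g: (-1, vaf) for g in CODING_GENES},
                           seed=base + 100 + i)
            )
        groups = {s.sample_id: s.group for s in specs}
        counts = cohort_count_table(panel, specs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = fit_all_backgrounds(counts, groups)
            calls = call_positives(counts, models, groups, min_vaf=min_vaf,
                                   targets=targets)
        planted = {(s.sample_id, g) for s in specs if s.group == "tumor"
                   for g in CODING_GENES}
        pos = calls[calls["positive"]]
        pos_keys = set(zip(pos["sample_id"], pos["locus_id"]))
        n_planted += len(planted)
        n_called += len(planted & pos_keys)
        n_pos_calls += len(pos_keys)
        n_true_calls += len(pos_keys & planted)
    return {
        "detection_rate": n_called / n_planted,
        "precision": (n_true_calls / n_pos_calls) if n_pos_calls else 1.0,
        "n_planted": n_planted,
    }


def detection_by_vaf(
    vafs: Sequence[float] = (0.05, 0.1, 0.2, 0.4),
    n_seeds: int = 10,
    seed: int = 0,
    **kwargs,
) -> dict[float, float]:
    return {
        v: power_study(vaf=v, n_seeds=n_seeds, seed=seed + int(v * 1000), **kwargs)[
            "detection_rate"
        ]
        for v in vafs
    }


def msi_panel_study(
    n_panels: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict:
    """Per-marker and MSI-H/MSS accuracy on 7-marker trace panels with
    0-7 planted unstable markers (shift 1-9 bp deletions)."""
    markers = make_locus_panel(MSI_MARKER_CONFIG, seed=0)
    rng = np.random.default_rng(seed)
    marker_ok = total_markers = label_ok = 0
    for _ in range(n_panels):
        n_unstable = int(rng.integers(0, 8))
        which = rng.choice(len(markers), size=n_unstable, replace=False)
        shifts = {markers[i].locus_id: int(rng.integers(1, 10)) for i in which}
        control = simulate_marker_traces(markers, {}, "wt", noise_sd=noise_sd,
                                         seed=int(rng.integers(2**31)))
        traces = simulate_marker_traces(markers, shifts, "s", noise_sd=noise_sd,
                                        seed=int(rng.integers(2**31)))
        rep = score_sample(traces, control, "s")
        for m in rep.marker_scores:
            truth = m.marker_id in shifts
            marker_ok += int(m.evaluable and m.unstable == truth)
            total_markers += 1
        truth_label = "MSI-H" if n_unstable >= 2 else "MSS"
        label_ok += int(rep.classification == truth_label)
    return {
        "marker_accuracy": marker_ok / total_markers,
        "label_accuracy": label_ok / n_panels,
        "n_panels": n_panels,
    }
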
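"""End-to-end orchestration: simulate -> count -> call -> msi -> hotspot.

A :class:`RunConfig` captures every threshold and seed; a run is a pure
function of the config, and the manifest records checksums of every output
so reruns can be verified byte-for-byte.

The bundled demo configuration emulates an MMRd characterisation study on
synthetic data: 10 organoid-like, 18 end-stage-tumor-like and 16
mucosa-like samples against 8 wild-type controls, sequenced over the five
coding mononucleotide-repeat targets, with a 7-marker fragment-analysis
MSI panel and a read-frequency hotspot assay.  The demo applies a 5%
minimum-VAF reporting floor on positive frameshift calls, a standard
effect-size guard in clinical amplicon assays (well above the <=2%
background VAFs the generator produces).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import counting, msi, report, simulate
from .calling import FrameshiftBackgroundModel
from .hotspot import call_mutations, calls_to_frame, top_common_reads
from .panel import RepeatLocus, default_panel, coding_panel, make_locus_panel
from .panel import MSI_MARKER_CONFIG


@dataclass
class RunConfig:
    """Thresholds, seeds and cohort layout for one pipeline run."""

    seed: int = 0
    cohort: str = "golden"          # "golden" or "null"
    depth: int = 2000
    stutter_rate: float = 0.02
    stutter_decay: float = 0.3
    subst_error_rate: float = 0.001
    # calling
    alpha: float = 0.05
    method: str = "predictive"
    min_vaf: float = 0.05
    targets_only: bool = True       # test only the assay's -1 coding targets
    # read processing
    max_primer_mismatches: int = 1
    flank_anchor_len: int = 6
    max_flank_mismatches: int = 0
    # MSI scoring
    msi_noise_sd: float = 0.0
    min_rel_height: float = 0.10
    min_separation_bp: int = 1
    tolerance_bp: int = 0
    # hotspot assay
    hotspot_top_k: int = 300
    hotspot_min_frequency: float = 0.04
    hotspot_depth: int = 1000

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _log(log: list, stage: str, **counts) -> None:
    log.append({"stage": stage, **counts})


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 overwrite: bool = False) -> dict:
    """Execute every stage and return the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    noise = dict(
        stutter_rate=config.stutter_rate, stutter_decay=config.stutter_decay,
        subst_error_rate=config.subst_error_rate,
    )

    # ---- simulate ---------------------------------------------------------
    panel = coding_panel(seed=config.seed)
    if config.cohort == "golden":
        specs = simulate.golden_cohort_specs(
            depth=config.depth, base_seed=config.seed, **noise
        )
    elif config.cohort == "null":
        specs = simulate.null_cohort_specs(
            depth=config.depth, base_seed=config.seed, **noise
        )
    else:
        raise ValueError(f"unknown cohort {config.cohort!r}")
    groups = {s.sample_id: s.group for s in specs}
    manifest = simulate.write_fixtures(panel, specs, out / "fixtures",
                                       overwrite=overwrite)
    _log(log, "simulate", n_samples=len(specs), n_loci=len(panel))

    # ---- count ------------------------------------------------------------
    obs_frames = []
    n_unassigned = n_unusable = n_reads = 0
    for spec in specs:
        reads = simulate.read_fastq(out / "fixtures" / f"{spec.sample_id}.fastq")
        n_reads += len(reads)
        frame = counting.count_reads(
            reads, panel, spec.sample_id,
            max_primer_mismatches=config.max_primer_mismatches,
            flank_anchor_len=config.flank_anchor_len,
            max_flank_mismatches=config.max_flank_mismatches,
        )
        n_unassigned += frame.attrs["n_unassigned"]
        n_unusable += frame.attrs["n_unusable"]
        obs_frames.append(frame)
    counts = counting.tabulate(pd.concat(obs_frames, ignore_index=True), panel)
    counting.write_count_table(counts, out / "counts.tsv")
    _log(log, "count", n_reads=n_reads, n_unassigned=n_unassigned,
         n_unusable=n_unusable, n_rows=len(counts))

    # ---- call -------------------------------------------------------------
    targets = (
        [(loc.locus_id, -1) for loc in panel] if config.targets_only else None
    )
    results = FrameshiftBackgroundModel(
        counts, groups, alpha=config.alpha, method=config.method,
        min_vaf=config.min_vaf, targets=targets,
    ).fit()
    results.save(out)
    freq = results.frequency_table()
    if not freq.empty:
        (out / "frequency_table.txt").write_text(
            report.render_frequency_table(
                freq,
                group_order=list(simulate.GOLDEN_GROUP_SIZES),
                group_sizes=simulate.GOLDEN_GROUP_SIZES
                if config.cohort == "golden" else None,
            )
            + "\n"
        )
    _log(log, "call", n_tests=len(results.calls), n_positive=results.n_positive)

    # ---- msi --------------------------------------------------------------
    markers = make_locus_panel(MSI_MARKER_CONFIG, seed=config.seed)
    rng = np.random.default_rng([config.seed, 0x4D53])  # "MS" stream for shifts
    control_traces = simulate.simulate_marker_traces(
        markers, {}, "WTpool", noise_sd=config.msi_noise_sd, seed=config.seed
    )
    msi_rows = []
    reports = {}
    for i, spec in enumerate(specs):
        if spec.group == "wt_control":
            continue
        is_tumor_like = config.cohort == "golden"
        if is_tumor_like:
            shifts = {
                m.locus_id: int(rng.integers(2, 9)) for m in markers
            }  # MSI-H: every marker shifted
        else:
            shifts = {}
        traces = simulate.simulate_marker_traces(
            markers, shifts, spec.sample_id, noise_sd=config.msi_noise_sd,
            seed=config.seed + 1000 + i,
        )
        rep = msi.score_sample(
            traces, control_traces, spec.sample_id,
            min_rel_height=config.min_rel_height,
            min_separation_bp=config.min_separation_bp,
            tolerance_bp=config.tolerance_bp,
        )
        reports[spec.sample_id] = rep
        msi_rows.append(rep.to_frame())
    msi_df = pd.concat(msi_rows, ignore_index=True) if msi_rows else pd.DataFrame()
    msi_df.to_csv(out / "msi_report.tsv", sep="\t", index=False)
    n_msih = sum(r.classification == "MSI-H" for r in reports.values())
    _log(log, "msi", n_samples=len(reports), n_msi_h=n_msih)

    # ---- hotspot ----------------------------------------------------------
    trp53 = make_locus_panel(
        [{"locus_id": "Trp53", "repeat_unit": "A", "wt_repeat_count": 6}],
        seed=config.seed + 7,
    )[0]
    reference = trp53.amplicon()
    mid = len(reference) // 2
    alt_base = "T" if reference[mid] != "T" else "G"
    variant = reference[:mid] + alt_base + reference[mid + 1:]
    reads = simulate.simulate_hotspot_reads(
        reference, {variant: 0.40}, depth=config.hotspot_depth,
        seed=config.seed + 11,
    )
    ranked = top_common_reads(reads, k=config.hotspot_top_k)
    hotspot_calls = call_mutations(
        ranked, reference, min_frequency=config.hotspot_min_frequency,
        locus_id="Trp53",
    )
    calls_to_frame(hotspot_calls).to_csv(out / "hotspot_calls.tsv", sep="\t",
                                         index=False)
    _log(log, "hotspot", n_ranked=len(ranked), n_calls=len(hotspot_calls))

    # ---- manifest ---------------------------------------------------------
    config.to_json(out / "config.json")
    outputs = [
        "counts.tsv", "calls.tsv", "frequencies.tsv", "backgrounds.tsv",
        "msi_report.tsv", "hotspot_calls.tsv", "config.json",
    ]
    run_manifest = {
        "config": dataclasses.asdict(config),
        "stages": log,
        "files": {name: _sha256(out / name) for name in outputs
                  if (out / name).exists()},
        "fixtures": manifest["files"],
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=1, sort_keys=True)
    return run_manifest
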
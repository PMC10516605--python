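"""Frameshift-positivity calling: background fits, FDR and cohort frequencies.

The workflow mirrors the targeted-sequencing analysis of coding
mononucleotide repeats in mismatch-repair-deficient tumors: per
(locus, offset) the VAF background is fitted from wild-type controls
(:mod:`msikit.background`), every tumor VAF receives an upper-tail
p-value, the whole tumor x indel family is Benjamini-Hochberg corrected in
one batch, and a sample is called positive when its adjusted q-value falls
below alpha (optionally also requiring a minimum VAF as an effect-size
reporting floor).  Cohort mutation frequencies per group reproduce the
familiar publication table: percent of samples positive per gene and
offset.

The statsmodels-style entry point is::

    res = FrameshiftBackgroundModel(counts, groups).fit()
    res.calls              # per (sample, locus, offset) p/q/positive
    res.frequency_table()  # per (locus, offset, group) percent positive
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .background import (
    WeibullBackground,
    background_pvalue,
    default_floor,
    fit_weibull_background,
)

CALL_COLUMNS = [
    "sample_id", "locus_id", "offset", "vaf",
    "mutant_reads", "wt_reads", "p_value", "q_value", "positive",
]

WT_CONTROL_GROUP = "wt_control"


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, in [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_all_backgrounds(
    count_table: pd.DataFrame,
    groups: Mapping[str, str],
    floor: float | None = None,
    n_min: int = 5,
    min_nonzero: int = 2,
    targets: Sequence[tuple[str, int]] | None = None,
) -> dict[tuple[str, int], WeibullBackground]:
    """Fit one Weibull background per (locus, offset) from the control rows.

    The zero-VAF floor defaults to half a read at the median control
    denominator depth, computed once across the table.
    """
    is_control = count_table["sample_id"].map(groups) == WT_CONTROL_GROUP
    controls = count_table[is_control]
    if controls.empty:
        raise ValueError("count table contains no wt_control samples")
    if floor is None:
        depths = (controls["mutant_reads"] + controls["wt_reads"]).to_numpy()
        floor = default_floor(depths[depths > 0])
    models: dict[tuple[str, int], WeibullBackground] = {}
    wanted = set(map(tuple, targets)) if targets is not None else None
    for (locus_id, offset), grp in controls.groupby(["locus_id", "offset"], sort=True):
        key = (locus_id, int(offset))
        if wanted is not None and key not in wanted:
            continue
        vafs = grp["vaf"].fillna(0.0).to_numpy()
        denom = (grp["mutant_reads"] + grp["wt_reads"]).sum()
        pooled = float(grp["mutant_reads"].sum() / denom) if denom > 0 else 0.0
        models[key] = fit_weibull_background(
            vafs, locus_id=locus_id, offset=int(offset), floor=floor,
            n_min=n_min, min_nonzero=min_nonzero, pooled_rate=pooled,
        )
    return models


def call_positives(
    count_table: pd.DataFrame,
    models: Mapping[tuple[str, int], WeibullBackground],
    groups: Mapping[str, str],
    alpha: float = 0.05,
    method: str = "predictive",
    min_vaf: float = 0.0,
    batch: str = "pooled",
    targets: Sequence[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Assign p/q-values and positivity to every tumor-side row.

    Wild-type controls are never tested against their own background.  The
    BH family is the full tumor x indel batch (``batch='pooled'``, the
    conservative default) or per sample (``batch='per_sample'``).
    ``positive`` means q < alpha, and additionally vaf >= min_vaf when an
    effect-size floor is configured.  Rows whose (locus, offset) has no
    fitted model are skipped with a warning.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    wanted = set(map(tuple, targets)) if targets is not None else None
    rows = []
    for rec in count_table.itertuples(index=False):
        if groups.get(rec.sample_id, "") == WT_CONTROL_GROUP:
            continue
        key = (rec.locus_id, int(rec.offset))
        if wanted is not None and key not in wanted:
            continue
        model = models.get(key)
        if model is None:
            warnings.warn(f"no background model for {key}; row skipped", stacklevel=2)
            continue
        vaf = 0.0 if pd.isna(rec.vaf) else float(rec.vaf)
        p = background_pvalue(
            model, vaf,
            mutant_reads=int(rec.mutant_reads),
            denom_reads=int(rec.mutant_reads + rec.wt_reads),
            method=method,
        )
        rows.append(
            {
                "sample_id": rec.sample_id, "locus_id": rec.locus_id,
                "offset": int(rec.offset), "vaf": vaf,
                "mutant_reads": int(rec.mutant_reads),
                "wt_reads": int(rec.wt_reads), "p_value": p,
            }
        )
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS[:-2])
    if calls.empty:
        calls["q_value"] = []
        calls["positive"] = []
        return calls
    if batch == "pooled":
        calls["q_value"] = fdr_adjust(calls["p_value"])
    elif batch == "per_sample":
        calls["q_value"] = np.nan
        for _sid, idx in calls.groupby("sample_id").groups.items():
            calls.loc[idx, "q_value"] = fdr_adjust(calls.loc[idx, "p_value"])
    else:
        raise ValueError(f"unknown batch mode {batch!r}")
    calls["positive"] = (calls["q_value"] < alpha) & (calls["vaf"] >= min_vaf)
    return calls


def mutation_frequency(calls: pd.DataFrame, groups: Mapping[str, str]) -> pd.DataFrame:
    """Percent of samples positive per (locus, offset, group).

    The denominator is the number of samples of the group with a tested row
    for the indel (no-coverage samples are absent from ``calls`` and hence
    excluded).  Empty groups are omitted.
    """
    if calls.empty:
        return pd.DataFrame(
            columns=["locus_id", "offset", "group", "n_samples", "n_positive",
                     "frequency"]
        )
    df = calls.copy()
    df["group"] = df["sample_id"].map(groups)
    if df["group"].isna().any():
        missing = sorted(df.loc[df["group"].isna(), "sample_id"].unique())
        raise ValueError(f"samples missing from the sample sheet: {missing}")
    out = (
        df.groupby(["locus_id", "offset", "group"], sort=True)
        .agg(n_samples=("positive", "size"), n_positive=("positive", "sum"))
        .reset_index()
    )
    out["n_positive"] = out["n_positive"].astype(int)
    out["frequency"] = out["n_positive"] / out["n_samples"]
    return out


# ---------------------------------------------------------------------------
# Model / Results objects

class FrameshiftBackgroundModel:
    """Frameshift-positivity model for an indel count table.

    Parameters
    ----------
    count_table : DataFrame
        IndelCountTable rows (sample_id, locus_id, offset, mutant_reads,
        wt_reads, total_usable, vaf).
    groups : mapping sample_id -> group
        Must label the controls as ``wt_control``.
    alpha : float
        Positivity threshold on BH-adjusted q-values.
    method : {"predictive", "plugin"}
        Tail-probability flavour (see :mod:`msikit.background`).
    min_vaf : float
        Effect-size reporting floor on positive calls (0 disables).
    targets : sequence of (locus_id, offset), optional
        Restrict testing to specific indels (e.g. the assay's -1 targets).
    """

    def __init__(
        self,
        count_table: pd.DataFrame,
        groups: Mapping[str, str],
        alpha: float = 0.05,
        method: str = "predictive",
        min_vaf: float = 0.0,
        floor: float | None = None,
        n_min: int = 5,
        min_nonzero: int = 2,
        batch: str = "pooled",
        targets: Sequence[tuple[str, int]] | None = None,
    ) -> None:
        self.count_table = count_table
        self.groups = dict(groups)
        self.alpha = alpha
        self.method = method
        self.min_vaf = min_vaf
        self.floor = floor
        self.n_min = n_min
        self.min_nonzero = min_nonzero
        self.batch = batch
        self.targets = list(map(tuple, targets)) if targets is not None else None

    @classmethod
    def from_files(cls, counts_tsv: str | Path, samples_tsv: str | Path,
                   **kwargs) -> "FrameshiftBackgroundModel":
        counts = pd.read_csv(counts_tsv, sep="\t")
        sheet = pd.read_csv(samples_tsv, sep="\t")
        groups = dict(zip(sheet["sample_id"], sheet["group"]))
        return cls(counts, groups, **kwargs)

    def fit(self) -> "FrameshiftCallResults":
        models = fit_all_backgrounds(
            self.count_table, self.groups, floor=self.floor, n_min=self.n_min,
            min_nonzero=self.min_nonzero, targets=self.targets,
        )
        calls = call_positives(
            self.count_table, models, self.groups, alpha=self.alpha,
            method=self.method, min_vaf=self.min_vaf, batch=self.batch,
            targets=self.targets,
        )
        return FrameshiftCallResults(self, models, calls)


class FrameshiftCallResults:
    """Fitted backgrounds plus the call matrix, with summary accessors."""

    def __init__(self, model: FrameshiftBackgroundModel,
                 backgrounds: Mapping[tuple[str, int], WeibullBackground],
                 calls: pd.DataFrame) -> None:
        self.model = model
        self.backgrounds = dict(backgrounds)
        self.calls = calls

    @property
    def n_positive(self) -> int:
        return int(self.calls["positive"].sum()) if len(self.calls) else 0

    def frequency_table(self) -> pd.DataFrame:
        return mutation_frequency(self.calls, self.model.groups)

    def background_table(self) -> pd.DataFrame:
        rows = [
            {
                "locus_id": m.locus_id, "offset": m.offset, "shape": m.shape,
                "scale": m.scale, "n_controls": m.n_controls,
                "floor": m.floor, "fit_ok": m.fit_ok,
                "degenerate": m.degenerate, "reason": m.reason,
            }
            for m in self.backgrounds.values()
        ]
        return pd.DataFrame(rows).sort_values(["locus_id", "offset"]).reset_index(
            drop=True
        )

    def summary(self) -> str:
        bt = self.background_table()
        lines = [
            "Frameshift background model".center(64),
            "=" * 64,
            f"tests: {len(self.calls)}   positives (q < {self.model.alpha:g}"
            + (f", vaf >= {self.model.min_vaf:g}" if self.model.min_vaf > 0 else "")
            + f"): {self.n_positive}",
            f"backgrounds fitted: {len(bt)}   "
            f"degenerate/unfit: {int((~bt['fit_ok'] | bt['degenerate']).sum())}",
            f"tail method: {self.model.method}   BH batch: {self.model.batch}",
            "-" * 64,
            f"{'locus':<14}{'offset':>7}{'shape':>9}{'scale':>11}{'n':>4}  flag",
        ]
        for r in bt.itertuples(index=False):
            flag = r.reason if (r.degenerate or not r.fit_ok) else ""
            lines.append(
                f"{r.locus_id:<14}{r.offset:>7d}{r.shape:>9.3f}{r.scale:>11.3g}"
                f"{r.n_controls:>4d}  {flag}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.calls.to_csv(out / "calls.tsv", sep="\t", index=False)
        self.frequency_table().to_csv(out / "frequencies.tsv", sep="\t", index=False)
        self.background_table().to_csv(out / "backgrounds.tsv", sep="\t", index=False)
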
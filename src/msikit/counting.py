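"""Amplicon read processing: primer trimming, repeat-length extraction and
per-indel count tables.

Amplicon structure makes full alignment unnecessary: reads are assigned to
loci by their forward-primer prefix, and the repeat length is read off
between two short flank anchors.  Reads whose anchors cannot be placed, or
whose inter-anchor sequence is not a pure repeat run of whole units, are
excluded as unusable rather than rescued.

The resulting table has one row per (sample, locus, offset != 0) with mutant
reads (observations at WT+offset repeat units), WT reads, and
VAF = mutant / (mutant + WT).  Offsets are zero-filled across samples: an
offset seen in any sample yields rows (possibly with VAF 0) for every sample
with coverage at that locus, so WT controls contribute explicit zeros for
tumor-only offsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import RepeatLocus, validate_panel

COUNT_COLUMNS = [
    "sample_id", "locus_id", "offset",
    "mutant_reads", "wt_reads", "total_usable", "vaf",
]


@dataclass(frozen=True)
class RepeatObservation:
    sample_id: str
    locus_id: str
    observed_repeat_count: int
    usable: bool
    reason: str = ""


def _hamming_within(a: str, b: str, budget: int) -> bool:
    """True if Hamming distance between equal-length strings <= budget."""
    if len(a) != len(b):
        return False
    mismatches = 0
    for x, y in zip(a, b):
        if x != y:
            mismatches += 1
            if mismatches > budget:
                return False
    return True


def trim_and_assign(
    read: str,
    panel: Sequence[RepeatLocus],
    max_primer_mismatches: int = 1,
    _primer_index: dict | None = None,
) -> tuple[str, str] | None:
    """Assign a read to the unique locus whose forward primer matches the
    read prefix within the mismatch budget; returns (locus_id, insert) with
    the primer removed, or None (empty read, no match, or ambiguous tie)."""
    if not read:
        return None
    if _primer_index is not None:  # exact fast path
        for plen, table in _primer_index.items():
            hit = table.get(read[:plen])
            if hit is not None:
                return hit.locus_id, read[len(hit.fwd_primer):]
    hits = [
        loc for loc in panel
        if len(read) >= len(loc.fwd_primer)
        and _hamming_within(read[: len(loc.fwd_primer)], loc.fwd_primer,
                            max_primer_mismatches)
    ]
    if len(hits) != 1:
        return None
    loc = hits[0]
    return loc.locus_id, read[len(loc.fwd_primer):]


def build_primer_index(panel: Sequence[RepeatLocus]) -> dict:
    """Exact-prefix lookup (primer length -> primer -> locus); validates the
    panel for duplicate primers."""
    validate_panel(panel)
    index: dict[int, dict[str, RepeatLocus]] = {}
    for loc in panel:
        index.setdefault(len(loc.fwd_primer), {})[loc.fwd_primer] = loc
    return index


def _find_anchor(insert: str, anchor: str, budget: int, start: int = 0) -> int:
    """Leftmost occurrence (index) of ``anchor`` in ``insert[start:]`` within
    a Hamming mismatch budget; -1 if absent."""
    if budget == 0:
        return insert.find(anchor, start)
    n, m = len(insert), len(anchor)
    for i in range(start, n - m + 1):
        if _hamming_within(insert[i : i + m], anchor, budget):
            return i
    return -1


def extract_repeat_count(
    insert: str,
    locus: RepeatLocus,
    sample_id: str = "",
    flank_anchor_len: int = 6,
    max_flank_mismatches: int = 0,
) -> RepeatObservation:
    """Read the repeat length between flank anchors.

    The anchor pair is the last ``flank_anchor_len`` bases of the left flank
    (leftmost occurrence) and the first ``flank_anchor_len`` bases of the
    right flank (first occurrence to the right of the left anchor).  The
    spanned sequence must be a pure run of whole repeat units (no mismatch
    allowed inside the tract); anything else is unusable, never an error.
    """
    if flank_anchor_len < 4:
        raise ValueError("flank_anchor_len must be >= 4")
    left_anchor = locus.left_flank[-flank_anchor_len:]
    right_anchor = locus.right_flank[:flank_anchor_len]
    li = _find_anchor(insert, left_anchor, max_flank_mismatches)
    if li < 0:
        return RepeatObservation(sample_id, locus.locus_id, -1, False, "no_left_anchor")
    tract_start = li + flank_anchor_len
    ri = _find_anchor(insert, right_anchor, max_flank_mismatches, start=tract_start)
    if ri < 0:
        return RepeatObservation(sample_id, locus.locus_id, -1, False, "no_right_anchor")
    tract = insert[tract_start:ri]
    unit = locus.repeat_unit
    if len(tract) % len(unit) != 0:
        return RepeatObservation(sample_id, locus.locus_id, -1, False, "partial_unit")
    n = len(tract) // len(unit)
    if tract != unit * n:
        return RepeatObservation(sample_id, locus.locus_id, -1, False, "impure_tract")
    return RepeatObservation(sample_id, locus.locus_id, n, True)


def count_reads(
    reads: Iterable[tuple[str, str]],
    panel: Sequence[RepeatLocus],
    sample_id: str,
    max_primer_mismatches: int = 1,
    flank_anchor_len: int = 6,
    max_flank_mismatches: int = 0,
) -> pd.DataFrame:
    """Aggregate reads of one sample into an observed-repeat-count histogram
    per locus: columns (sample_id, locus_id, observed_repeat_count, n_reads).
    Unassigned/unusable reads are tallied under ``attrs['n_unassigned']`` and
    ``attrs['n_unusable']``."""
    index = build_primer_index(panel)
    by_locus = {loc.locus_id: loc for loc in panel}
    hist: dict[tuple[str, int], int] = {}
    n_unassigned = n_unusable = 0
    for _read_id, seq in reads:
        assigned = trim_and_assign(seq, panel, max_primer_mismatches, index)
        if assigned is None:
            n_unassigned += 1
            continue
        locus_id, insert = assigned
        obs = extract_repeat_count(
            insert, by_locus[locus_id], sample_id, flank_anchor_len,
            max_flank_mismatches,
        )
        if not obs.usable:
            n_unusable += 1
            continue
        key = (locus_id, obs.observed_repeat_count)
        hist[key] = hist.get(key, 0) + 1
    df = pd.DataFrame(
        [
            {"sample_id": sample_id, "locus_id": k[0],
             "observed_repeat_count": k[1], "n_reads": v}
            for k, v in sorted(hist.items())
        ],
        columns=["sample_id", "locus_id", "observed_repeat_count", "n_reads"],
    )
    df.attrs["n_unassigned"] = n_unassigned
    df.attrs["n_unusable"] = n_unusable
    return df


def histogram_frame(sample_id: str, locus_id: str,
                    hist: Mapping[int, int]) -> pd.DataFrame:
    """Adapter: observed-count histogram dict -> count_reads-shaped frame."""
    return pd.DataFrame(
        [
            {"sample_id": sample_id, "locus_id": locus_id,
             "observed_repeat_count": int(k), "n_reads": int(v)}
            for k, v in sorted(hist.items())
        ],
        columns=["sample_id", "locus_id", "observed_repeat_count", "n_reads"],
    )


def tabulate(
    observation_counts: pd.DataFrame,
    panel: Sequence[RepeatLocus],
) -> pd.DataFrame:
    """Observed-count histograms -> per-indel count table (IndelCountTable).

    For each locus, the offset set is the union of nonzero offsets observed
    in ANY sample; each sample with coverage at the locus gets a row per
    offset (zero-filled).  Samples without usable reads at a locus are
    omitted (no-coverage).  VAF = mutant / (mutant + WT); a row where both
    are zero has VAF 0 by the zero-fill contract.
    """
    wt_by_locus = {loc.locus_id: loc.wt_repeat_count for loc in panel}
    rows = []
    for locus_id, ldf in observation_counts.groupby("locus_id", sort=True):
        wt = wt_by_locus[locus_id]
        offsets = sorted(
            int(c) - wt for c in ldf["observed_repeat_count"].unique() if int(c) != wt
        )
        if not offsets:
            continue
        for sample_id, sdf in ldf.groupby("sample_id", sort=True):
            counts = dict(
                zip(sdf["observed_repeat_count"].astype(int), sdf["n_reads"].astype(int))
            )
            total = int(sdf["n_reads"].sum())
            if total == 0:
                continue
            wt_reads = counts.get(wt, 0)
            for off in offsets:
                mut = counts.get(wt + off, 0)
                denom = mut + wt_reads
                rows.append(
                    {
                        "sample_id": sample_id, "locus_id": locus_id, "offset": off,
                        "mutant_reads": mut, "wt_reads": wt_reads,
                        "total_usable": total,
                        "vaf": (mut / denom) if denom > 0 else np.nan,
                    }
                )
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def count_cohort(
    sample_reads: Mapping[str, Iterable[tuple[str, str]]],
    panel: Sequence[RepeatLocus],
    **kwargs,
) -> pd.DataFrame:
    """Count several samples and tabulate into one IndelCountTable."""
    frames = [
        count_reads(reads, panel, sample_id, **kwargs)
        for sample_id, reads in sample_reads.items()
    ]
    obs = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["sample_id", "locus_id", "observed_repeat_count", "n_reads"]
    )
    return tabulate(obs, panel)


def write_count_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
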
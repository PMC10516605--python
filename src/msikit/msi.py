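"""Fragment-analysis MSI scoring.

Capillary-electrophoresis traces enter as (size_bp, intensity) tables on an
integer 1-bp grid.  Scoring follows clinical fragment-analysis practice:

* peaks are local maxima above a relative-height threshold;
* a marker is *unstable* in a sample if its dominant peak is shifted by at
  least 1 bp relative to the matched wild-type control, or if the sample
  shows peaks absent from the control ("new peaks");
* the shift magnitude is reported in the "mN" notation (m4 = dominant peak
  4 bp away from the control's);
* a sample is MSI-high (MSI-H) with instability at >= 2 panel markers and
  microsatellite-stable (MSS) with instability at <= 1 marker.

Stutter ladders (PCR slippage artifacts at -1, -2, ... bp below a true
allele) are suppressed before the new-peak rule is applied, so that the
artifact ladder of a tall allele is not miscalled as instability.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class TraceError(ValueError):
    pass


@dataclass(frozen=True)
class Electropherogram:
    """A fragment-analysis trace for one (sample, marker)."""

    sample_id: str
    marker_id: str
    sizes_bp: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes_bp, dtype=int)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "sizes_bp", sizes)
        object.__setattr__(self, "intensities", inten)
        if sizes.shape != inten.shape or sizes.ndim != 1:
            raise TraceError("sizes and intensities must be 1-D and equal length")
        if len(sizes) and not np.all(np.diff(sizes) == 1):
            raise TraceError("trace must be on a strictly increasing 1-bp grid")
        if np.any(inten < 0):
            raise TraceError("intensities must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"size_bp": self.sizes_bp, "intensity": self.intensities})

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str, marker_id: str) -> "Electropherogram":
        df = pd.read_csv(path, sep="\t")
        return cls(sample_id, marker_id, df["size_bp"].to_numpy(),
                   df["intensity"].to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Peak:
    size_bp: int
    height: float
    relative_height: float


@dataclass(frozen=True)
class PeakSet:
    peaks: tuple[Peak, ...]

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self):
        return len(self.peaks)

    @property
    def sizes(self) -> list[int]:
        return [p.size_bp for p in self.peaks]

    def dominant(self) -> Peak:
        """Tallest peak; ties broken toward smaller size (deletion-biased
        slippage makes the smaller product the biologically dominant call)."""
        if not self.peaks:
            raise TraceError("empty peak set has no dominant peak")
        return min(self.peaks, key=lambda p: (-p.height, p.size_bp))


def detect_peaks(trace: Electropherogram, min_rel_height: float = 0.10,
                 min_separation_bp: int = 1) -> PeakSet:
    """Call peaks: grid points >= ``min_rel_height`` of the trace maximum.

    Every integer fragment size is a distinct PCR product, so any grid
    point above the analytic threshold is a peak candidate (a stutter
    shoulder adjacent to a tall allele is a real product and must be
    reportable for downstream stutter handling).  Candidates are accepted
    tallest-first; one closer than ``min_separation_bp`` to an accepted
    peak is suppressed.  Equal heights at sufficient separation are all
    kept.  Deterministic: ties in height are processed smaller-size-first.
    """
    if not 0 < min_rel_height < 1:
        raise TraceError("min_rel_height must be in (0, 1)")
    y = trace.intensities
    if len(y) == 0 or y.max() <= 0:
        return PeakSet(())
    top = y.max()
    cand = [i for i in range(len(y)) if y[i] >= min_rel_height * top]
    cand.sort(key=lambda i: (-y[i], trace.sizes_bp[i]))
    accepted: list[int] = []
    for i in cand:
        if all(abs(int(trace.sizes_bp[i]) - int(trace.sizes_bp[j])) >= max(min_separation_bp, 1)
               for j in accepted):
            accepted.append(i)
    accepted.sort(key=lambda i: trace.sizes_bp[i])
    peaks = tuple(
        Peak(int(trace.sizes_bp[i]), float(y[i]), float(y[i] / top)) for i in accepted
    )
    return PeakSet(peaks)


@dataclass(frozen=True)
class MarkerScore:
    marker_id: str
    evaluable: bool
    unstable: bool = False
    shift_magnitude: int = 0
    new_peak_sizes: tuple[int, ...] = ()


def _suppress_stutter(peaks: PeakSet, window_bp: int = 2,
                      rel_height: float = 0.5) -> list[Peak]:
    """Drop peaks within ``window_bp`` of a taller peak and under
    ``rel_height`` of its height: these are PCR stutter shoulders, not new
    alleles.  Slippage is deletion-biased but plus-stutter products are real
    too, so the window is applied on both sides of the parent peak."""
    kept = []
    for p in peaks:
        is_stutter = any(
            0 < abs(q.size_bp - p.size_bp) <= window_bp
            and p.height < rel_height * q.height
            for q in peaks
        )
        if not is_stutter:
            kept.append(p)
    return kept


def score_marker(
    sample_peaks: PeakSet,
    control_peaks: PeakSet,
    marker_id: str = "",
    tolerance_bp: int = 0,
    stutter_window_bp: int = 2,
    stutter_rel_height: float = 0.5,
) -> MarkerScore:
    """Score one marker against its matched wild-type control.

    Positivity requires at least a 1-bp shift of the dominant peak, or a
    (non-stutter) sample peak with no control peak within ``tolerance_bp``.
    """
    if len(control_peaks) == 0:
        raise TraceError("control peak set must be non-empty")
    if len(sample_peaks) == 0:
        return MarkerScore(marker_id, evaluable=False)
    dom_s = sample_peaks.dominant()
    dom_c = control_peaks.dominant()
    shift = abs(dom_s.size_bp - dom_c.size_bp)
    control_sizes = control_peaks.sizes
    new_peaks = tuple(
        p.size_bp
        for p in _suppress_stutter(sample_peaks, stutter_window_bp, stutter_rel_height)
        if all(abs(p.size_bp - c) > tolerance_bp for c in control_sizes)
    )
    unstable = shift >= 1 or len(new_peaks) > 0
    return MarkerScore(marker_id, True, unstable, shift, new_peaks)


@dataclass(frozen=True)
class MSIReport:
    sample_id: str
    marker_scores: tuple[MarkerScore, ...]

    @property
    def evaluable_scores(self) -> list[MarkerScore]:
        return [m for m in self.marker_scores if m.evaluable]

    @property
    def n_unstable(self) -> int:
        return sum(m.unstable for m in self.evaluable_scores)

    @property
    def classification(self) -> str:
        if len(self.evaluable_scores) < 2:
            return "unevaluable"
        return "MSI-H" if self.n_unstable >= 2 else "MSS"

    @property
    def shift_profile(self) -> dict[str, int]:
        return {m.marker_id: m.shift_magnitude for m in self.evaluable_scores}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": self.sample_id,
                "marker_id": m.marker_id,
                "evaluable": m.evaluable,
                "unstable": m.unstable,
                "shift_magnitude": m.shift_magnitude,
                "new_peak_sizes": ",".join(map(str, m.new_peak_sizes)),
                "n_unstable": self.n_unstable,
                "classification": self.classification,
            }
            for m in self.marker_scores
        ]
        return pd.DataFrame(rows)


def classify_msi(sample_id: str, marker_scores: Iterable[MarkerScore]) -> MSIReport:
    """MSI-H with instability at >= 2 evaluable markers, MSS otherwise;
    fewer than 2 evaluable markers makes the sample unevaluable."""
    return MSIReport(sample_id, tuple(marker_scores))


def score_sample(
    sample_traces: Mapping[str, Electropherogram],
    control_traces: Mapping[str, Electropherogram],
    sample_id: str,
    min_rel_height: float = 0.10,
    min_separation_bp: int = 1,
    tolerance_bp: int = 0,
    stutter_window_bp: int = 2,
    stutter_rel_height: float = 0.5,
) -> MSIReport:
    """End-to-end per-sample scoring over the shared marker set."""
    scores = []
    for marker in sorted(set(sample_traces) & set(control_traces)):
        sp = detect_peaks(sample_traces[marker], min_rel_height, min_separation_bp)
        cp = detect_peaks(control_traces[marker], min_rel_height, min_separation_bp)
        scores.append(
            score_marker(sp, cp, marker, tolerance_bp, stutter_window_bp,
                         stutter_rel_height)
        )
    return classify_msi(sample_id, scores)


def compare_profiles(report_a: MSIReport, report_b: MSIReport) -> pd.DataFrame:
    """Per-marker shift deltas between two samples (e.g. parental organoid
    vs serially passaged tumor).  ``delta = m_b - m_a``; the comparison
    carries an ``increased_instability`` flag true iff the median delta > 0.
    """
    pa, pb = report_a.shift_profile, report_b.shift_profile
    shared = sorted(set(pa) & set(pb))
    if not shared:
        raise TraceError("profiles share no markers")
    rows = [
        {"marker_id": m, "m_a": pa[m], "m_b": pb[m], "delta": pb[m] - pa[m]}
        for m in shared
    ]
    df = pd.DataFrame(rows)
    df.attrs["increased_instability"] = bool(statistics.median(df["delta"]) > 0)
    return df
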
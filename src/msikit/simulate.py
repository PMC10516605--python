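"""Synthetic data generator: PCR-stutter amplicon reads and fragment traces.

The read model emulates targeted amplicon sequencing over mononucleotide
repeats.  Each read derives from either the wild-type template or (with
probability ``true_vaf``) a planted frameshift template, then acquires

* *stutter*: with probability ``stutter_rate`` the observed repeat length
  slips; the slip sign is equiprobable and its magnitude is geometric with
  parameter ``1 - stutter_decay`` (so P(|slip|=m) decays as
  ``stutter_decay**(m-1)``).  Slippage applies identically to WT and mutant
  templates — the mutant allele carries its own stutter ladder.
* uniform substitution errors at ``subst_error_rate`` per base, never
  placed in the 6 bp of flank on either side of the repeat tract (keeps
  flank anchoring decoupled from the error model; a stated simplification).

Reads are single-end and span the whole amplicon.  All randomness flows
from explicit integer seeds; the same seed reproduces byte-identical
output.

Electropherograms are synthesised per allele as a main peak plus a stutter
ladder at +/- k bp with relative height ``stutter_rate * stutter_decay**(k-1)``,
plus non-negative baseline noise.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .msi import Electropherogram
from .panel import RepeatLocus, write_panel

PROTECTED_FLANK_BP = 6

TRUTH_COLUMNS = ["sample_id", "locus_id", "offset", "true_vaf", "true_msi_unstable"]


class SimulationError(ValueError):
    pass


@dataclass
class SampleSpec:
    """Simulation recipe for one sample.

    ``planted_indels`` maps locus_id -> (offset in repeat units, true VAF).
    ``locus_depths`` overrides ``depth`` per locus; a value of 0 drops the
    locus from the sample entirely (no-coverage dropout).
    """

    sample_id: str
    group: str = "tumor"
    depth: int = 2000
    planted_indels: dict[str, tuple[int, float]] = field(default_factory=dict)
    stutter_rate: float = 0.02
    stutter_decay: float = 0.3
    subst_error_rate: float = 0.001
    seed: int = 0
    locus_depths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group == "wt_control" and self.planted_indels:
            raise SimulationError("wt_control samples cannot carry planted indels")
        for locus_id, (offset, vaf) in self.planted_indels.items():
            if not 0.0 <= vaf <= 1.0:
                raise SimulationError(f"true_vaf for {locus_id} outside [0,1]: {vaf}")
            if int(offset) == 0:
                raise SimulationError("planted offset must be nonzero")
        if not 0.0 <= self.stutter_rate <= 1.0:
            raise SimulationError("stutter_rate must be in [0,1]")
        if not 0.0 < self.stutter_decay < 1.0:
            raise SimulationError("stutter_decay must be in (0,1)")

    def depth_for(self, locus_id: str) -> int:
        return int(self.locus_depths.get(locus_id, self.depth))


def _locus_rng(spec: SampleSpec, locus: RepeatLocus) -> np.random.Generator:
    # independent, reproducible stream per (sample seed, locus)
    return np.random.default_rng([spec.seed, zlib.crc32(locus.locus_id.encode())])


def draw_slips(rng: np.random.Generator, n: int, stutter_rate: float,
               stutter_decay: float) -> np.ndarray:
    """Vector of signed slips (in repeat units) under the geometric model."""
    slips = np.zeros(n, dtype=int)
    slipped = rng.random(n) < stutter_rate
    k = int(slipped.sum())
    if k:
        mags = rng.geometric(1.0 - stutter_decay, size=k)
        signs = rng.choice([-1, 1], size=k)
        slips[slipped] = mags * signs
    return slips


def simulate_repeat_count_histogram(
    locus: RepeatLocus, spec: SampleSpec, rng: np.random.Generator | None = None
) -> dict[int, int]:
    """Observed-repeat-count histogram for one (sample, locus), bypassing
    sequence generation.  Exactly the read-level model marginalised over
    substitution errors (i.e. ``subst_error_rate = 0``); used for large
    statistical simulations where per-read sequences are irrelevant.
    """
    depth = spec.depth_for(locus.locus_id)
    if depth < 1:
        raise SimulationError("depth must be >= 1")
    if rng is None:
        rng = _locus_rng(spec, locus)
    offset, vaf = spec.planted_indels.get(locus.locus_id, (0, 0.0))
    n_mut = rng.binomial(depth, vaf) if vaf > 0 else 0
    true_counts = np.full(depth, locus.wt_repeat_count, dtype=int)
    true_counts[:n_mut] += int(offset)
    observed = np.maximum(
        true_counts + draw_slips(rng, depth, spec.stutter_rate, spec.stutter_decay), 0
    )
    vals, cnts = np.unique(observed, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, cnts)}


def _apply_substitutions(seq: str, locus: RepeatLocus, observed_count: int,
                         rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    # protected zones: the PROTECTED_FLANK_BP of flank anchoring each side of
    # the tract (the tract itself may acquire errors; the purity check then
    # drops the read as unusable)
    tract_start = len(locus.fwd_primer) + len(locus.left_flank)
    tract_end = tract_start + len(locus.repeat_unit) * observed_count
    allowed = [
        i for i in range(len(seq))
        if not (tract_start - PROTECTED_FLANK_BP <= i < tract_start
                or tract_end <= i < tract_end + PROTECTED_FLANK_BP)
    ]
    if not allowed:
        return seq
    positions = rng.choice(len(allowed), size=min(n_err, len(allowed)), replace=False)
    chars = list(seq)
    for p in positions:
        i = allowed[int(p)]
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[int(rng.integers(3))]
    return "".join(chars)


def simulate_reads(
    locus: RepeatLocus, spec: SampleSpec
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate ``(read_id, sequence)`` pairs for one (sample, locus), plus
    the truth-table rows for any planted indel at this locus."""
    depth = spec.depth_for(locus.locus_id)
    if depth < 1:
        raise SimulationError("depth must be >= 1")
    rng = _locus_rng(spec, locus)
    offset, vaf = spec.planted_indels.get(locus.locus_id, (0, 0.0))
    is_mut = rng.random(depth) < vaf if vaf > 0 else np.zeros(depth, bool)
    base = locus.wt_repeat_count
    true_counts = np.where(is_mut, base + int(offset), base)
    observed = np.maximum(
        true_counts + draw_slips(rng, depth, spec.stutter_rate, spec.stutter_decay), 0
    )
    reads = []
    for i, obs in enumerate(observed):
        seq = locus.amplicon(int(obs))
        seq = _apply_substitutions(seq, locus, int(obs), spec.subst_error_rate, rng)
        reads.append((f"{spec.sample_id}:{locus.locus_id}:{i}", seq))
    truth = pd.DataFrame(
        [
            {
                "sample_id": spec.sample_id,
                "locus_id": locus.locus_id,
                "offset": int(offset),
                "true_vaf": float(vaf),
                "true_msi_unstable": True,
            }
        ]
        if locus.locus_id in spec.planted_indels
        else [],
        columns=TRUTH_COLUMNS,
    )
    return reads, truth


def simulate_sample(
    panel: Sequence[RepeatLocus], spec: SampleSpec
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """All reads for a sample across the panel (dropout loci skipped)."""
    reads: list[tuple[str, str]] = []
    truths = []
    for locus in panel:
        if spec.depth_for(locus.locus_id) == 0:
            continue
        r, t = simulate_reads(locus, spec)
        reads.extend(r)
        if not t.empty:
            truths.append(t)
    truth = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame(columns=TRUTH_COLUMNS)
    )
    return reads, truth


# ---------------------------------------------------------------------------
# Electropherogram synthesis

def simulate_electropherogram(
    locus: RepeatLocus,
    allele_fractions: Mapping[int, float],
    stutter_rate: float = 0.0,
    stutter_decay: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "",
    half_window_bp: int = 15,
) -> Electropherogram:
    """Trace on a 1-bp grid around the WT product size.

    Each allele at fractional abundance f contributes a main peak of height
    f plus a symmetric stutter ladder: height ``f * stutter_rate *
    stutter_decay**(k-1)`` at +/- k bp.  Baseline noise is Gaussian clipped
    at zero with scale ``noise_sd``.
    """
    total = sum(allele_fractions.values())
    if abs(total - 1.0) > 1e-6:
        raise SimulationError(f"allele fractions must sum to 1, got {total}")
    center = locus.product_size_wt
    sizes = np.arange(center - half_window_bp, center + half_window_bp + 1)
    intensity = np.zeros_like(sizes, dtype=float)
    for size_bp, frac in allele_fractions.items():
        for k in range(-half_window_bp, half_window_bp + 1):
            h = frac if k == 0 else frac * stutter_rate * stutter_decay ** (abs(k) - 1)
            pos = size_bp + k
            idx = np.nonzero(sizes == pos)[0]
            if len(idx) and h > 0:
                intensity[idx[0]] += h
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = np.clip(intensity + rng.normal(0.0, noise_sd, len(sizes)), 0.0, None)
    return Electropherogram(sample_id, locus.locus_id, sizes, intensity)


# ---------------------------------------------------------------------------
# Fixture writing

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path,
                quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_fixtures(
    panel: Sequence[RepeatLocus],
    samples: Sequence[SampleSpec],
    out_dir: str | Path,
    traces: Mapping[str, Mapping[str, Electropherogram]] | None = None,
    overwrite: bool = False,
) -> dict:
    """Write FASTA panel, per-sample FASTQ, truth TSV, trace TSVs and a JSON
    manifest with seeds and checksums.  Refuses to clobber an existing
    manifest unless ``overwrite`` is set."""
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)

    files: dict[str, str] = {}
    write_panel(panel, out / "panel.fasta", out / "panel.json")
    files["panel.fasta"] = _sha256(out / "panel.fasta")
    files["panel.json"] = _sha256(out / "panel.json")

    truths = []
    for spec in samples:
        reads, truth = simulate_sample(panel, spec)
        fq = out / f"{spec.sample_id}.fastq"
        write_fastq(reads, fq)
        files[fq.name] = _sha256(fq)
        if not truth.empty:
            truths.append(truth)
    truth_df = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame(
        columns=TRUTH_COLUMNS
    )
    truth_df.to_csv(out / "truth.tsv", sep="\t", index=False)
    files["truth.tsv"] = _sha256(out / "truth.tsv")

    sheet = pd.DataFrame(
        [{"sample_id": s.sample_id, "group": s.group} for s in samples]
    )
    sheet.to_csv(out / "samples.tsv", sep="\t", index=False)
    files["samples.tsv"] = _sha256(out / "samples.tsv")

    if traces:
        tdir = out / "traces"
        tdir.mkdir(exist_ok=True)
        for sample_id, by_marker in traces.items():
            for marker_id, trace in by_marker.items():
                tp = tdir / f"{sample_id}__{marker_id}.tsv"
                trace.to_tsv(tp)
                files[f"traces/{tp.name}"] = _sha256(tp)

    manifest = {
        "n_samples": len(samples),
        "seeds": {s.sample_id: s.seed for s in samples},
        "files": files,
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Cohort builders

def control_specs(n: int = 8, depth: int = 2000, base_seed: int = 0,
                  stutter_rate: float = 0.02, stutter_decay: float = 0.3,
                  subst_error_rate: float = 0.001) -> list[SampleSpec]:
    return [
        SampleSpec(
            sample_id=f"WT{i+1:02d}", group="wt_control", depth=depth,
            stutter_rate=stutter_rate, stutter_decay=stutter_decay,
            subst_error_rate=subst_error_rate, seed=base_seed + i,
        )
        for i in range(n)
    ]


def null_cohort_specs(n_controls: int = 8, n_tumors: int = 10, depth: int = 2000,
                      base_seed: int = 0, **noise) -> list[SampleSpec]:
    """All-null cohort: WT controls plus WT-like 'tumors' with no planted
    events — the configuration used to audit type-I error."""
    specs = control_specs(n_controls, depth, base_seed, **noise)
    specs += [
        SampleSpec(
            sample_id=f"T{i+1:02d}", group="tumor", depth=depth,
            seed=base_seed + n_controls + i, **noise,
        )
        for i in range(n_tumors)
    ]
    return specs


# Planted positives for the Table-1-shaped golden cohort.  Counts per group
# are chosen so the truth frequencies reproduce a realistic MMRd cohort table
# (with per-locus coverage dropouts where the printed percentage implies a
# smaller denominator: 75% = 6/8, 12.5% = 2/16, 7.1% = 1/14).
GOLDEN_PLAN = {
    # gene: (vaf, {group: (n_positive, n_dropout)})
    "Asxl1": (0.40, {"organoid": (10, 0), "end_stage_tumor": (17, 0), "mucosa": (16, 0)}),
    "Maz": (0.12, {"organoid": (2, 0), "end_stage_tumor": (2, 2), "mucosa": (1, 2)}),
    "Xirp1": (0.35, {"organoid": (10, 0), "end_stage_tumor": (18, 0), "mucosa": (16, 0)}),
    "Senp6": (0.35, {"organoid": (10, 0), "end_stage_tumor": (17, 0), "mucosa": (16, 0)}),
    "Nacad": (0.30, {"organoid": (6, 2), "end_stage_tumor": (17, 0), "mucosa": (16, 0)}),
}

GOLDEN_GROUP_SIZES = {"organoid": 10, "end_stage_tumor": 18, "mucosa": 16}


def golden_cohort_specs(depth: int = 2000, base_seed: int = 0,
                        n_controls: int = 8, **noise) -> list[SampleSpec]:
    """Demo cohort shaped like an MMRd mouse-organoid characterisation study:
    10 organoid-like, 18 end-stage-tumor-like and 16 mucosa-like samples
    plus WT controls, with -1 frameshifts planted at the five coding targets
    so the truth frequency table matches the demo plan by construction."""
    specs = control_specs(n_controls, depth, base_seed, **noise)
    seed = base_seed + n_controls
    for group, size in GOLDEN_GROUP_SIZES.items():
        for i in range(size):
            planted: dict[str, tuple[int, float]] = {}
            locus_depths: dict[str, int] = {}
            for gene, (vaf, plan) in GOLDEN_PLAN.items():
                n_pos, n_drop = plan[group]
                if i >= size - n_drop:
                    locus_depths[gene] = 0  # coverage dropout
                elif i < n_pos:
                    planted[gene] = (-1, vaf)
            specs.append(
                SampleSpec(
                    sample_id=f"{group[:3].upper()}{i+1:02d}", group=group,
                    depth=depth, planted_indels=planted,
                    locus_depths=locus_depths, seed=seed, **noise,
                )
            )
            seed += 1
    return specs


def simulate_marker_traces(
    markers: Sequence[RepeatLocus],
    shifts_bp: Mapping[str, int],
    sample_id: str,
    stutter_rate: float = 0.1,
    stutter_decay: float = 0.5,
    noise_sd: float = 0.0,
    shifted_fraction: float = 0.7,
    seed: int = 0,
) -> dict[str, Electropherogram]:
    """Fragment-analysis traces for one sample over a marker panel.

    ``shifts_bp[marker] = s > 0`` plants an unstable marker whose dominant
    allele is s bp below the WT product (deletion-biased slippage), mixed
    with residual WT signal; s = 0 (or absent) leaves the marker stable.
    """
    traces = {}
    for i, marker in enumerate(markers):
        s = int(shifts_bp.get(marker.locus_id, 0))
        wt_size = marker.product_size_wt
        if s > 0:
            fractions = {wt_size - s: shifted_fraction,
                         wt_size: 1.0 - shifted_fraction}
        else:
            fractions = {wt_size: 1.0}
        traces[marker.locus_id] = simulate_electropherogram(
            marker, fractions, stutter_rate, stutter_decay, noise_sd,
            seed=seed + i, sample_id=sample_id,
        )
    return traces


def simulate_hotspot_reads(
    reference: str,
    variant_fractions: Mapping[str, float],
    depth: int = 1000,
    seed: int = 0,
) -> list[str]:
    """Reads for the read-frequency hotspot assay: each key of
    ``variant_fractions`` is a full variant read sequence carried by exactly
    ``round(fraction * depth)`` reads, the remainder being wild type.  The
    read order is shuffled deterministically from the seed."""
    counts = {seq: round(frac * depth) for seq, frac in variant_fractions.items()}
    if sum(counts.values()) > depth:
        raise SimulationError("variant fractions exceed the requested depth")
    reads = [reference] * (depth - sum(counts.values()))
    for seq, c in counts.items():
        reads.extend([seq] * c)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def golden_truth_frequencies() -> pd.DataFrame:
    """Truth frequency table implied by :data:`GOLDEN_PLAN` (percent)."""
    rows = []
    for gene, (_vaf, plan) in GOLDEN_PLAN.items():
        for group, size in GOLDEN_GROUP_SIZES.items():
            n_pos, n_drop = plan[group]
            n_eval = size - n_drop
            rows.append(
                {
                    "locus_id": gene, "offset": -1, "group": group,
                    "n_samples": n_eval, "n_positive": n_pos,
                    "frequency": n_pos / n_eval,
                }
            )
    return pd.DataFrame(rows)
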
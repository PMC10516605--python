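"""Amplicon panel definitions for mononucleotide-repeat targets.

A panel is a list of :class:`RepeatLocus` records, each describing one PCR
amplicon over a microsatellite: primers, flanking sequence, the repeat unit
and its wild-type copy number.  Amplicons are laid out as

    fwd_primer + left_flank + unit * wt_repeat_count + right_flank + rev_primer

on a single strand.  Flank/primer sequences in the built-in demo panels are
synthetic (seeded random DNA), not genomic sequence; locus names follow the
mouse MSI marker panel (L24372, U12235, Bat30/37/59/64/67) and the coding
mononucleotide-repeat genes recurrently frameshifted in mismatch-repair
deficient tumors (Asxl1, Maz, Xirp1, Senp6, Nacad).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_DNA = set("ACGT")


class PanelError(ValueError):
    """Raised for invalid locus definitions or panel-level inconsistencies."""


def _check_dna(name: str, seq: str, min_len: int = 1) -> None:
    if len(seq) < min_len:
        raise PanelError(f"{name} must be at least {min_len} nt, got {len(seq)}")
    if not set(seq) <= _DNA:
        raise PanelError(f"{name} contains non-ACGT characters: {seq!r}")


@dataclass(frozen=True)
class RepeatLocus:
    """One amplicon target over a mononucleotide (or short-unit) repeat.

    The repeat run must be maximal: the left flank may not end with the
    repeat unit and the right flank may not start with it, so the observed
    run length is unambiguous.
    """

    locus_id: str
    left_flank: str
    repeat_unit: str
    wt_repeat_count: int
    right_flank: str
    fwd_primer: str
    rev_primer: str

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise PanelError("locus_id must be non-empty")
        _check_dna("repeat_unit", self.repeat_unit, 1)
        if self.wt_repeat_count < 5:
            raise PanelError(
                f"{self.locus_id}: wt_repeat_count must be >= 5, got {self.wt_repeat_count}"
            )
        _check_dna("left_flank", self.left_flank, 15)
        _check_dna("right_flank", self.right_flank, 15)
        _check_dna("fwd_primer", self.fwd_primer, 1)
        _check_dna("rev_primer", self.rev_primer, 1)
        if self.left_flank.endswith(self.repeat_unit):
            raise PanelError(
                f"{self.locus_id}: left_flank ends with repeat unit; repeat run not maximal"
            )
        if self.right_flank.startswith(self.repeat_unit):
            raise PanelError(
                f"{self.locus_id}: right_flank starts with repeat unit; repeat run not maximal"
            )

    @property
    def repeat_tract(self) -> str:
        return self.repeat_unit * self.wt_repeat_count

    @property
    def product_size_wt(self) -> int:
        """Length in bp of the full wild-type amplicon."""
        return (
            len(self.fwd_primer)
            + len(self.left_flank)
            + len(self.repeat_unit) * self.wt_repeat_count
            + len(self.right_flank)
            + len(self.rev_primer)
        )

    def amplicon(self, repeat_count: int | None = None) -> str:
        """Full amplicon sequence with ``repeat_count`` repeat units (WT default)."""
        n = self.wt_repeat_count if repeat_count is None else repeat_count
        if n < 0:
            raise PanelError("repeat_count must be >= 0")
        return (
            self.fwd_primer
            + self.left_flank
            + self.repeat_unit * n
            + self.right_flank
            + self.rev_primer
        )

    @property
    def insert_wt(self) -> str:
        """WT amplicon with the forward primer removed (what trimming yields)."""
        return self.left_flank + self.repeat_tract + self.right_flank + self.rev_primer


def _random_dna(rng: np.random.Generator, n: int, forbid_first: str = "",
                forbid_last: str = "") -> str:
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=n))
    if forbid_first:
        choices = [b for b in "ACGT" if b != forbid_first]
        if seq[0] == forbid_first:
            seq[0] = choices[int(rng.integers(len(choices)))]
    if forbid_last:
        choices = [b for b in "ACGT" if b != forbid_last]
        if seq[-1] == forbid_last:
            seq[-1] = choices[int(rng.integers(len(choices)))]
    return "".join(seq)


def make_locus_panel(
    panel_config: Sequence[Mapping],
    seed: int = 0,
    flank_len: int = 20,
    primer_len: int = 20,
) -> list[RepeatLocus]:
    """Build a validated panel from per-locus configs.

    Each config requires ``locus_id``, ``repeat_unit`` and ``wt_repeat_count``;
    ``left_flank``/``right_flank``/``fwd_primer``/``rev_primer`` may be given
    explicitly, otherwise they are generated from the seed (deterministically,
    respecting repeat-run maximality).  Duplicate forward primers are rejected
    because read assignment keys on them.
    """
    rng = np.random.default_rng(seed)
    loci = []
    for cfg in panel_config:
        unit = cfg["repeat_unit"]
        if not unit:
            raise PanelError("repeat_unit must be non-empty")
        left = cfg.get("left_flank") or _random_dna(rng, flank_len, forbid_last=unit[0])
        right = cfg.get("right_flank") or _random_dna(rng, flank_len, forbid_first=unit[-1])
        fwd = cfg.get("fwd_primer") or _random_dna(rng, primer_len)
        rev = cfg.get("rev_primer") or _random_dna(rng, primer_len)
        loci.append(
            RepeatLocus(
                locus_id=cfg["locus_id"],
                left_flank=left,
                repeat_unit=unit,
                wt_repeat_count=int(cfg["wt_repeat_count"]),
                right_flank=right,
                fwd_primer=fwd,
                rev_primer=rev,
            )
        )
    validate_panel(loci)
    return loci


def validate_panel(panel: Sequence[RepeatLocus]) -> None:
    ids = [loc.locus_id for loc in panel]
    if len(set(ids)) != len(ids):
        raise PanelError("duplicate locus_id in panel")
    primers = [loc.fwd_primer for loc in panel]
    if len(set(primers)) != len(primers):
        raise PanelError("duplicate forward primers in panel")


# Demo panel: 7 fragment-analysis MSI markers + 5 coding MNR targets.
# Repeat copy numbers for the coding targets are demo values of a realistic
# magnitude for coding mononucleotide runs; marker tract lengths follow the
# marker names where they encode one (U12235-A24, L24372-A27).
MSI_MARKER_CONFIG = [
    {"locus_id": "mU12235-A24", "repeat_unit": "A", "wt_repeat_count": 24},
    {"locus_id": "mL24372-A27", "repeat_unit": "A", "wt_repeat_count": 27},
    {"locus_id": "mBat64", "repeat_unit": "A", "wt_repeat_count": 34},
    {"locus_id": "mBat30", "repeat_unit": "A", "wt_repeat_count": 30},
    {"locus_id": "mBat37", "repeat_unit": "A", "wt_repeat_count": 37},
    {"locus_id": "mBat59", "repeat_unit": "A", "wt_repeat_count": 40},
    {"locus_id": "mBat67", "repeat_unit": "A", "wt_repeat_count": 42},
]

CODING_TARGET_CONFIG = [
    {"locus_id": "Asxl1", "repeat_unit": "G", "wt_repeat_count": 8},
    {"locus_id": "Maz", "repeat_unit": "C", "wt_repeat_count": 9},
    {"locus_id": "Xirp1", "repeat_unit": "A", "wt_repeat_count": 10},
    {"locus_id": "Senp6", "repeat_unit": "A", "wt_repeat_count": 9},
    {"locus_id": "Nacad", "repeat_unit": "C", "wt_repeat_count": 8},
]


def default_panel(seed: int = 0) -> list[RepeatLocus]:
    """The bundled demo panel: 7 MSI markers plus 5 coding MNR targets."""
    return make_locus_panel(MSI_MARKER_CONFIG + CODING_TARGET_CONFIG, seed=seed)


def coding_panel(seed: int = 0) -> list[RepeatLocus]:
    """Just the 5 coding MNR targets (frameshift sequencing assay)."""
    return make_locus_panel(CODING_TARGET_CONFIG, seed=seed)


# ---------------------------------------------------------------------------
# I/O: FASTA of WT amplicons + JSON sidecar with the structured fields.

def write_panel(panel: Sequence[RepeatLocus], fasta_path: str | Path,
                json_path: str | Path | None = None) -> None:
    fasta_path = Path(fasta_path)
    json_path = Path(json_path) if json_path else fasta_path.with_suffix(".json")
    records = [
        SeqRecord(Seq(loc.amplicon()), id=loc.locus_id,
                  description=f"wt_amplicon len={loc.product_size_wt}")
        for loc in panel
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(json_path, "w") as fh:
        json.dump([asdict(loc) for loc in panel], fh, indent=1)


def read_panel(json_path: str | Path) -> list[RepeatLocus]:
    with open(json_path) as fh:
        data = json.load(fh)
    panel = [RepeatLocus(**d) for d in data]
    validate_panel(panel)
    return panel
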
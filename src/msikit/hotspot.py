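"""Read-frequency hotspot mutation calling (Trp53-style assay).

The caller ranks the distinct read sequences of a sample by abundance,
globally aligns the top-ranked reads to the wild-type reference amplicon,
and reports every edit carried by reads whose summed frequency exceeds a
threshold (default: strictly greater than 4% of all assigned reads).

Alignment is Needleman-Wunsch with unit mismatch/gap costs and fully
deterministic tie-breaking (substitution preferred over gaps, deletion
over insertion); equivalent indel placements are normalised to the
leftmost position, so a deletion inside a homopolymer is always reported
at the start of the run (the usual left-alignment convention for variant
reporting).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class RankedRead:
    sequence: str
    count: int
    frequency: float
    rank: int


@dataclass(frozen=True)
class Edit:
    """One mutation against the reference.

    ``kind`` is "sub", "ins" or "del"; ``position`` is 1-based on the
    reference (for insertions, the base after which the sequence is
    inserted; position 0 means an insertion before the first base).
    """

    kind: str
    position: int
    ref: str
    alt: str


@dataclass(frozen=True)
class MutationCall:
    locus_id: str
    edit: Edit
    frequency: float
    supporting_ranks: tuple[int, ...]


def top_common_reads(reads: Iterable[str], k: int = 300) -> list[RankedRead]:
    """Rank distinct sequences by count (ties lexicographic) and keep the
    top ``k``; frequencies are relative to ALL reads, not the top-k subset."""
    if k < 1:
        raise ValueError("k must be >= 1")
    seqs = list(reads)
    total = len(seqs)
    if total == 0:
        return []
    counts = Counter(seqs)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        RankedRead(seq, c, c / total, rank)
        for rank, (seq, c) in enumerate(ordered[:k], start=1)
    ]


_SUB, _DEL, _INS = 0, 1, 2  # traceback codes; order encodes tie preference


def _needleman_wunsch(read: str, ref: str) -> list[tuple[str, int]]:
    """Global alignment path as (op, ref_index) steps, ops in
    {match, sub, del, ins}.  Unit costs; ties prefer substitution, then
    deletion, then insertion."""
    n, m = len(ref), len(read)
    # D[i, j]: cost aligning ref[:i] with read[:j]
    D = np.zeros((n + 1, m + 1), dtype=np.int32)
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    steps = np.arange(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        prev = D[i - 1]
        # candidate without the insertion move
        a = np.empty(m + 1, dtype=np.int32)
        a[0] = i
        a[1:] = np.minimum(prev[:-1] + (ref_arr[i - 1] != read_arr), prev[1:] + 1)
        # insertion closes under a prefix running minimum with unit slope:
        # D[i, j] = min_{t<=j} (a[t] + (j - t))
        D[i] = np.minimum.accumulate(a - steps) + steps
    # traceback with deterministic preference sub > del > ins
    path: list[tuple[str, int]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            diag = D[i - 1, j - 1] + (ref[i - 1] != read[j - 1])
            if diag == D[i, j]:
                path.append(("match" if ref[i - 1] == read[j - 1] else "sub", i))
                i, j = i - 1, j - 1
                continue
        if i > 0 and D[i - 1, j] + 1 == D[i, j]:
            path.append(("del", i))
            i -= 1
            continue
        path.append(("ins", i))
        j -= 1
    path.reverse()
    return path


def _path_to_edits(path: Sequence[tuple[str, int]], read: str, ref: str) -> list[Edit]:
    edits: list[Edit] = []
    j = 0  # read cursor
    pending_ins: list[str] = []
    pending_ins_pos = 0
    pending_del: list[str] = []
    pending_del_pos = 0

    def flush_ins() -> None:
        nonlocal pending_ins
        if pending_ins:
            edits.append(Edit("ins", pending_ins_pos, "", "".join(pending_ins)))
            pending_ins = []

    def flush_del() -> None:
        nonlocal pending_del
        if pending_del:
            edits.append(Edit("del", pending_del_pos, "".join(pending_del), ""))
            pending_del = []

    for op, ref_pos in path:
        if op in ("match", "sub"):
            flush_ins()
            flush_del()
            if op == "sub":
                edits.append(Edit("sub", ref_pos, ref[ref_pos - 1], read[j]))
            j += 1
        elif op == "del":
            flush_ins()
            if not pending_del:
                pending_del_pos = ref_pos
            pending_del.append(ref[ref_pos - 1])
        else:  # ins
            flush_del()
            if not pending_ins:
                pending_ins_pos = ref_pos
            pending_ins.append(read[j])
            j += 1
    flush_ins()
    flush_del()
    return edits


def _left_align(edit: Edit, ref: str) -> Edit:
    """Shift an indel to its leftmost equivalent placement on the reference."""
    if edit.kind == "del":
        pos, seq = edit.position, list(edit.ref)
        # deleting ref[pos-1 .. pos+L-2]; can shift left while the base just
        # before equals the last base of the deleted window
        while pos > 1 and ref[pos - 2] == seq[-1]:
            seq.insert(0, ref[pos - 2])
            seq.pop()
            pos -= 1
        return Edit("del", pos, "".join(seq), "")
    if edit.kind == "ins":
        pos, seq = edit.position, list(edit.alt)
        # inserted after ref[pos-1]; can shift left while ref[pos-1] equals
        # the last inserted base (rotate)
        while pos > 0 and ref[pos - 1] == seq[-1]:
            seq.insert(0, seq.pop())
            pos -= 1
        return Edit("ins", pos, "", "".join(seq))
    return edit


def align_to_reference(read_sequence: str, reference: str) -> list[Edit]:
    """Edit script of a read against the reference amplicon: global
    alignment, indels left-aligned, deterministic."""
    if not read_sequence or not reference:
        raise ValueError("sequences must be non-empty")
    if read_sequence == reference:
        return []
    path = _needleman_wunsch(read_sequence, reference)
    edits = _path_to_edits(path, read_sequence, reference)
    return sorted(
        (_left_align(e, reference) for e in edits),
        key=lambda e: (e.position, e.kind, e.alt, e.ref),
    )


def call_mutations(
    ranked_reads: Sequence[RankedRead],
    reference: str,
    min_frequency: float = 0.04,
    locus_id: str = "",
) -> list[MutationCall]:
    """Report every edit whose supporting read frequency strictly exceeds
    ``min_frequency``, summed over the ranked reads that carry it."""
    support: dict[Edit, float] = {}
    ranks: dict[Edit, list[int]] = {}
    cache: dict[str, list[Edit]] = {}
    for rr in ranked_reads:
        if rr.sequence not in cache:
            cache[rr.sequence] = align_to_reference(rr.sequence, reference)
        for edit in cache[rr.sequence]:
            support[edit] = support.get(edit, 0.0) + rr.frequency
            ranks.setdefault(edit, []).append(rr.rank)
    calls = [
        MutationCall(locus_id, e, f, tuple(sorted(ranks[e])))
        for e, f in support.items()
        if f > min_frequency
    ]
    calls.sort(key=lambda c: (-c.frequency, c.edit.position, c.edit.kind))
    return calls


def calls_to_frame(calls: Sequence[MutationCall]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "locus_id": c.locus_id, "position": c.edit.position,
                "kind": c.edit.kind, "ref": c.edit.ref, "alt": c.edit.alt,
                "frequency": c.frequency,
                "n_supporting_reads": len(c.supporting_ranks),
            }
            for c in calls
        ],
        columns=["locus_id", "position", "kind", "ref", "alt", "frequency",
                 "n_supporting_reads"],
    )
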
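import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msikit.hotspot import (
    Edit,
    align_to_reference,
    call_mutations,
    top_common_reads,
)


class TestTopCommonReads:
    def test_single_sequence_frequency_one(self):
        rr = top_common_reads(["ACGT"] * 100)
        assert len(rr) == 1
        assert rr[0].frequency == 1.0 and rr[0].count == 100 and rr[0].rank == 1

    def test_top_k_with_frequencies_over_all_reads(self):
        reads = ["AAA"] * 50 + ["CCC"] * 30 + ["GGG"] * 20
        rr = top_common_reads(reads, k=2)
        assert [(r.sequence, r.frequency) for r in rr] == [("AAA", 0.5), ("CCC", 0.3)]

    def test_ties_broken_lexicographically(self):
        rr = top_common_reads(["TTT"] * 5 + ["AAA"] * 5)
        assert [r.sequence for r in rr] == ["AAA", "TTT"]
        assert [r.rank for r in rr] == [1, 2]

    def test_empty_and_invalid(self):
        assert top_common_reads([]) == []
        with pytest.raises(ValueError):
            top_common_reads(["A"], k=0)

    def test_frequencies_sum_to_at_most_one(self):
        rng = np.random.default_rng(0)
        reads = ["".join(rng.choice(list("ACGT"), 5)) for _ in range(500)]
        rr = top_common_reads(reads, k=100)
        assert sum(r.frequency for r in rr) <= 1.0 + 1e-12
        rr_all = top_common_reads(reads, k=10_000)
        assert sum(r.frequency for r in rr_all) == pytest.approx(1.0)


def brute_force_optimal_scripts(read: str, ref: str):
    """Enumerate every minimum-cost global alignment (for tiny inputs) and
    return the set of edit scripts, one per alignment."""
    n, m = len(ref), len(read)
    D = np.zeros((n + 1, m + 1), dtype=int)
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = min(
                D[i - 1, j - 1] + (ref[i - 1] != read[j - 1]),
                D[i - 1, j] + 1,
                D[i, j - 1] + 1,
            )

    scripts = set()

    def walk(i, j, acc):
        if i == 0 and j == 0:
            scripts.add(tuple(reversed(acc)))
            return
        if i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + (ref[i - 1] != read[j - 1]):
            step = () if ref[i - 1] == read[j - 1] else (("sub", i, read[j - 1]),)
            walk(i - 1, j - 1, acc + list(step))
        if i > 0 and D[i, j] == D[i - 1, j] + 1:
            walk(i - 1, j, acc + [("del", i, ref[i - 1])])
        if j > 0 and D[i, j] == D[i, j - 1] + 1:
            walk(i, j - 1, acc + [("ins", i, read[j - 1])])

    walk(n, m, [])
    return scripts


class TestAlignment:
    def test_identity_empty_script(self):
        assert align_to_reference("ACGTACGT", "ACGTACGT") == []

    def test_single_substitution_position(self):
        ref = "ACGTACGTACGTACG"
        read = ref[:9] + "G" + ref[10:]
        assert read[9] != ref[9]
        edits = align_to_reference(read, ref)
        assert edits == [Edit("sub", 10, ref[9], "G")]

    def test_homopolymer_deletion_reported_leftmost(self):
        ref = "CCTAAAAGG"
        read = "CCTAAAGG"  # one A of the A4 run deleted
        edits = align_to_reference(read, ref)
        assert edits == [Edit("del", 4, "A", "")]
        # oracle: position 4 is the leftmost deletion among ALL optimal
        # alignments enumerated by brute force
        scripts = brute_force_optimal_scripts(read, ref)
        del_positions = [
            op[1] for script in scripts for op in script
            if op[0] == "del" and len(script) == 1
        ]
        assert min(del_positions) == 4

    def test_homopolymer_insertion_reported_leftmost(self):
        ref = "CCTAAAAGG"
        read = "CCTAAAAAGG"
        edits = align_to_reference(read, ref)
        assert len(edits) == 1 and edits[0].kind == "ins"
        assert edits[0].position == 3  # inserted before the run
        assert edits[0].alt == "A"

    @pytest.mark.parametrize("read,ref", [
        ("ACCTG", "ACTG"), ("ACTG", "ACCTG"), ("AATTT", "ATTTT"),
        ("GGCAC", "GGCCAC"), ("TTTT", "TATT"),
    ])
    def test_cost_matches_brute_force(self, read, ref):
        edits = align_to_reference(read, ref)
        scripts = brute_force_optimal_scripts(read, ref)
        optimal_cost = min(len(s) for s in scripts) if scripts else 0
        assert len(edits) == optimal_cost

    @given(st.text(alphabet="ACGT", min_size=1, max_size=8),
           st.text(alphabet="ACGT", min_size=1, max_size=8))
    @settings(max_examples=80, deadline=None)
    def test_edit_count_equals_levenshtein(self, read, ref):
        edits = align_to_reference(read, ref)
        cost = sum(
            len(e.ref) if e.kind == "del" else len(e.alt) if e.kind == "ins" else 1
            for e in edits
        )
        D = brute_force_optimal_scripts(read, ref)
        lev = min(len(s) for s in D) if D else 0
        assert cost == lev


REF = "ACGTTGCAGGCTATCGATCG"


@pytest.fixture(scope="module")
def ref():
    return REF


class TestCallMutations:
    def _reads(self, ref, fractions, total=1000):
        reads = []
        for seq, frac in fractions.items():
            reads += [seq] * int(round(frac * total))
        reads += [ref] * (total - len(reads))
        return reads

    def test_threshold_is_strict(self, ref):
        v5 = "C" + ref[1:]
        assert v5[0] != ref[0]
        # 5% -> reported; exactly 4% -> not (strictly greater than)
        for frac, expect in [(0.05, 1), (0.04, 0), (0.03, 0)]:
            ranked = top_common_reads(self._reads(ref, {v5: frac}))
            calls = call_mutations(ranked, ref)
            assert len(calls) == expect

    def test_reference_identical_sample_no_calls(self, ref):
        ranked = top_common_reads([ref] * 200)
        assert call_mutations(ranked, ref) == []

    def test_shared_substitution_sums_across_reads(self, ref):
        # two distinct reads share one substitution: 4% + 2% -> 6%
        shared = "T" + ref[1:]
        assert shared[0] != ref[0]
        other = shared[:-1] + ("A" if ref[-1] != "A" else "C")
        ranked = top_common_reads(self._reads(ref, {shared: 0.04, other: 0.02}))
        calls = call_mutations(ranked, ref)
        shared_edit = Edit("sub", 1, ref[0], "T")
        by_edit = {c.edit: c for c in calls}
        assert by_edit[shared_edit].frequency == pytest.approx(0.06)
        assert len(by_edit[shared_edit].supporting_ranks) == 2

    def test_calls_invariant_under_read_order(self, ref):
        variant = ref[:5] + "A" + ref[6:]
        reads = self._reads(ref, {variant: 0.3})
        rng = np.random.default_rng(1)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        c1 = call_mutations(top_common_reads(reads), ref)
        c2 = call_mutations(top_common_reads(shuffled), ref)
        assert c1 == c2

    def test_planted_frequency_grid(self, ref):
        # variants at 1/3/5/40%: only the 5% and 40% cross the >4% threshold
        variants = {}
        positions = [2, 5, 8, 11]
        for pos, frac in zip(positions, [0.01, 0.03, 0.05, 0.40]):
            alt = "A" if ref[pos] != "A" else "G"
            variants[ref[:pos] + alt + ref[pos + 1:]] = frac
        ranked = top_common_reads(self._reads(ref, variants))
        calls = call_mutations(ranked, ref)
        called_pos = sorted(c.edit.position for c in calls)
        assert called_pos == [9, 12]  # 1-based positions of the 5% and 40%
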
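import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msikit.counting import (
    build_primer_index,
    count_reads,
    extract_repeat_count,
    histogram_frame,
    tabulate,
    trim_and_assign,
)
from msikit.simulate import SampleSpec, simulate_sample


class TestTrimAndAssign:
    def test_exact_match_assigns_and_trims(self, tiny_panel):
        loc = tiny_panel[0]
        insert = loc.insert_wt
        assigned = trim_and_assign(loc.fwd_primer + insert, tiny_panel, 0)
        assert assigned == (loc.locus_id, insert)

    def test_mismatch_budget_boundary(self, tiny_panel):
        loc = tiny_panel[0]
        primer = list(loc.fwd_primer)
        primer[3] = "A" if primer[3] != "A" else "C"
        read = "".join(primer) + loc.insert_wt
        assert trim_and_assign(read, tiny_panel, 1)[0] == loc.locus_id
        assert trim_and_assign(read, tiny_panel, 0) is None

    def test_empty_read_unassigned(self, tiny_panel):
        assert trim_and_assign("", tiny_panel, 2) is None

    def test_ambiguous_match_unassigned(self):
        from msikit.panel import make_locus_panel

        panel = make_locus_panel(
            [
                {"locus_id": "x", "repeat_unit": "A", "wt_repeat_count": 8,
                 "fwd_primer": "ACGTACGTACGTACGTACGA"},
                {"locus_id": "y", "repeat_unit": "T", "wt_repeat_count": 8,
                 "fwd_primer": "ACGTACGTACGTACGTACGC"},
            ],
            seed=0,
        )
        # one mismatch from both primers -> tie -> unassigned
        read = "ACGTACGTACGTACGTACGG" + panel[0].insert_wt
        assert trim_and_assign(read, panel, 1) is None

    def test_assignment_matches_simulator_truth(self, tiny_panel):
        # reads carry their source locus in the read id
        n_checked = 0
        for spec_seed in (1, 2):
            spec = SampleSpec("s", "tumor", depth=2500, seed=spec_seed,
                              subst_error_rate=0.001)
            reads, _ = simulate_sample(tiny_panel, spec)
            index = build_primer_index(tiny_panel)
            for read_id, seq in reads:
                res = trim_and_assign(seq, tiny_panel, 2, index)
                if res is not None:
                    assert res[0] == read_id.split(":")[1]
                    n_checked += 1
        assert n_checked > 4000  # nearly everything assigns at budget 2


class TestExtractRepeatCount:
    def test_wt_insert_yields_wt_count(self, tiny_panel):
        loc = tiny_panel[0]
        obs = extract_repeat_count(loc.insert_wt, loc)
        assert obs.usable and obs.observed_repeat_count == loc.wt_repeat_count

    def test_minus_one_deletion_detected(self, tiny_panel):
        loc = tiny_panel[0]
        insert = (loc.left_flank + loc.repeat_unit * (loc.wt_repeat_count - 1)
                  + loc.right_flank + loc.rev_primer)
        obs = extract_repeat_count(insert, loc)
        assert obs.usable
        assert obs.observed_repeat_count == loc.wt_repeat_count - 1

    def test_missing_anchor_unusable_not_exception(self, tiny_panel):
        loc = tiny_panel[0]
        obs = extract_repeat_count("GGGG", loc)
        assert not obs.usable and obs.reason == "no_left_anchor"

    def test_impure_tract_unusable(self, tiny_panel):
        loc = tiny_panel[0]
        tract = list(loc.repeat_tract)
        tract[3] = "G" if tract[3] != "G" else "C"
        insert = loc.left_flank + "".join(tract) + loc.right_flank
        obs = extract_repeat_count(insert, loc)
        assert not obs.usable and obs.reason == "impure_tract"

    def test_observed_distribution_equals_slip_distribution(self, tiny_panel):
        # with no substitution errors every read is usable and the observed
        # histogram equals a direct recount of the simulated sequences
        loc = tiny_panel[0]
        spec = SampleSpec("s", "tumor", depth=5000, seed=3,
                          stutter_rate=0.1, stutter_decay=0.4,
                          subst_error_rate=0.0)
        reads, _ = simulate_sample([loc], spec)
        frame = count_reads(reads, [loc], "s")
        assert frame.attrs["n_unassigned"] == 0
        assert frame.attrs["n_unusable"] == 0
        fixed = loc.product_size_wt - loc.wt_repeat_count
        expected = pd.Series(
            [len(seq) - fixed for _rid, seq in reads]
        ).value_counts().to_dict()
        got = dict(zip(frame["observed_repeat_count"], frame["n_reads"]))
        assert got == expected


class TestTabulate:
    def test_vaf_arithmetic(self, tiny_panel):
        loc = tiny_panel[0]
        wt = loc.wt_repeat_count
        obs = histogram_frame("s1", loc.locus_id, {wt: 980, wt - 1: 20})
        table = tabulate(obs, tiny_panel)
        row = table[(table["offset"] == -1)].iloc[0]
        assert row["mutant_reads"] == 20
        assert row["vaf"] == pytest.approx(20 / 1000)

    def test_zero_fill_across_samples(self, tiny_panel):
        loc = tiny_panel[0]
        wt = loc.wt_repeat_count
        obs = pd.concat([
            histogram_frame("tumor", loc.locus_id, {wt: 900, wt - 1: 100}),
            histogram_frame("ctrl", loc.locus_id, {wt: 1000}),
        ], ignore_index=True)
        table = tabulate(obs, tiny_panel)
        ctrl_row = table[(table["sample_id"] == "ctrl")].iloc[0]
        assert ctrl_row["offset"] == -1
        assert ctrl_row["mutant_reads"] == 0 and ctrl_row["vaf"] == 0.0

    def test_conservation_of_usable_reads(self, tiny_panel):
        spec = SampleSpec("s", "tumor", depth=3000, seed=5, stutter_rate=0.05,
                          subst_error_rate=0.0)
        reads, _ = simulate_sample(tiny_panel, spec)
        frame = count_reads(reads, tiny_panel, "s")
        assert frame["n_reads"].sum() == len(reads)
        table = tabulate(frame, tiny_panel)
        for _, grp in table.groupby("locus_id"):
            assert (grp["total_usable"] == grp["total_usable"].iloc[0]).all()

    @given(
        wt_reads=st.integers(0, 5000),
        mut_reads=st.integers(0, 5000),
    )
    @settings(max_examples=50, deadline=None)
    def test_vaf_bounds_property(self, tiny_panel, wt_reads, mut_reads):
        loc = tiny_panel[0]
        wt = loc.wt_repeat_count
        hist = {wt: wt_reads, wt - 1: mut_reads}
        hist = {k: v for k, v in hist.items() if v > 0}
        if not hist:
            return
        table = tabulate(histogram_frame("s", loc.locus_id, hist), tiny_panel)
        if table.empty:  # only WT reads -> no offsets
            assert mut_reads == 0
            return
        vafs = table["vaf"].dropna()
        assert ((vafs >= 0) & (vafs <= 1)).all()

    def test_noise_free_vaf_recovers_planted_exactly(self, tiny_panel):
        # depth * vaf integral, no stutter/errors -> recovered VAF is exact
        loc = tiny_panel[0]
        spec = SampleSpec("s", "tumor", depth=1000, seed=8, stutter_rate=0.0,
                          subst_error_rate=0.0,
                          planted_indels={loc.locus_id: (-1, 0.25)})
        reads, _ = simulate_sample([loc], spec)
        table = tabulate(count_reads(reads, [loc], "s"), [loc])
        vaf = table[table["offset"] == -1]["vaf"].iloc[0]
        # binomial sampling still applies to the per-read choice; exactness
        # holds for the identity VAF = mutant/(mutant+wt) on whatever was drawn
        counts = pd.Series([len(s) for _r, s in reads]).value_counts()
        n_mut = counts.get(loc.product_size_wt - 1, 0)
        assert vaf == pytest.approx(n_mut / 1000)
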
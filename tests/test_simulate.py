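import json

import numpy as np
import pytest

from msikit.msi import Electropherogram
from msikit.simulate import (
    SampleSpec,
    SimulationError,
    draw_slips,
    simulate_electropherogram,
    simulate_reads,
    simulate_repeat_count_histogram,
    simulate_sample,
    write_fixtures,
)


def run_length(seq: str, locus) -> int:
    """Independent read-out of the repeat run from the raw sequence."""
    fixed = locus.product_size_wt - len(locus.repeat_unit) * locus.wt_repeat_count
    return (len(seq) - fixed) // len(locus.repeat_unit)


class TestReadSimulation:
    def test_noise_free_reads_are_wild_type(self, locus_a24):
        spec = SampleSpec("s", "tumor", depth=200, stutter_rate=0.0,
                          subst_error_rate=0.0, seed=3)
        reads, truth = simulate_reads(locus_a24, spec)
        assert len(reads) == 200
        assert truth.empty
        assert all(seq == locus_a24.amplicon() for _rid, seq in reads)

    def test_planted_fraction_matches_binomial_oracle(self, locus_a24):
        # depth 10^4, -1 at VAF 0.5, no stutter: observed mutant fraction
        # within 3 binomial SDs of 0.5
        depth, vaf = 10_000, 0.5
        spec = SampleSpec("s", "tumor", depth=depth,
                          planted_indels={locus_a24.locus_id: (-1, vaf)},
                          stutter_rate=0.0, subst_error_rate=0.0, seed=7)
        reads, truth = simulate_reads(locus_a24, spec)
        frac = np.mean([
            run_length(seq, locus_a24) == locus_a24.wt_repeat_count - 1
            for _rid, seq in reads
        ])
        sd = np.sqrt(vaf * (1 - vaf) / depth)
        assert abs(frac - vaf) < 3 * sd
        assert truth.iloc[0]["offset"] == -1
        assert truth.iloc[0]["true_vaf"] == vaf

    def test_stutter_magnitudes_follow_geometric_decay(self, rng):
        # P(|slip| = 2) / P(|slip| = 1) ~= decay
        slips = draw_slips(rng, 2_000_000, stutter_rate=0.05, stutter_decay=0.3)
        n1, n2 = np.sum(np.abs(slips) == 1), np.sum(np.abs(slips) == 2)
        assert n2 / n1 == pytest.approx(0.3, rel=0.05)
        # signs equiprobable
        assert np.sum(slips > 0) / np.sum(slips != 0) == pytest.approx(0.5, abs=0.01)

    def test_histogram_shortcut_matches_read_level_model(self, locus_a24):
        # the count-level generator is the read-level model marginalised
        # over substitution errors: moments must agree at large depth
        spec = SampleSpec("s", "tumor", depth=100_000,
                          planted_indels={locus_a24.locus_id: (-1, 0.3)},
                          stutter_rate=0.05, stutter_decay=0.3,
                          subst_error_rate=0.0, seed=5)
        hist = simulate_repeat_count_histogram(locus_a24, spec)
        assert sum(hist.values()) == 100_000
        reads, _ = simulate_reads(locus_a24, SampleSpec(
            "s2", "tumor", depth=100_000,
            planted_indels={locus_a24.locus_id: (-1, 0.3)},
            stutter_rate=0.05, stutter_decay=0.3, subst_error_rate=0.0, seed=6))
        read_counts = np.array([run_length(s, locus_a24) for _r, s in reads])
        wt = locus_a24.wt_repeat_count
        for count in (wt, wt - 1, wt - 2):
            p_hist = hist.get(count, 0) / 100_000
            p_read = np.mean(read_counts == count)
            sd = np.sqrt(max(p_hist, 1e-9) / 100_000) * 2
            assert p_hist == pytest.approx(p_read, abs=6 * sd + 1e-4)

    def test_same_seed_identical_output(self, locus_a24):
        spec = dict(sample_id="s", group="tumor", depth=100, seed=9,
                    planted_indels={locus_a24.locus_id: (-1, 0.2)})
        r1, _ = simulate_reads(locus_a24, SampleSpec(**spec))
        r2, _ = simulate_reads(locus_a24, SampleSpec(**spec))
        assert r1 == r2

    @pytest.mark.parametrize("bad", [
        dict(depth=0),
        dict(planted_indels={"mU12235-A24": (-1, 1.5)}),
        dict(planted_indels={"mU12235-A24": (0, 0.5)}),
    ])
    def test_invalid_specs_rejected(self, locus_a24, bad):
        kwargs = dict(sample_id="s", group="tumor", depth=10, seed=0)
        kwargs.update(bad)
        with pytest.raises(SimulationError):
            spec = SampleSpec(**kwargs)
            simulate_reads(locus_a24, spec)

    def test_wt_control_cannot_carry_indels(self):
        with pytest.raises(SimulationError):
            SampleSpec("c", "wt_control", planted_indels={"Asxl1": (-1, 0.2)})


class TestElectropherogram:
    def test_single_allele_noise_free_single_point(self, locus_a24):
        tr = simulate_electropherogram(locus_a24, {locus_a24.product_size_wt: 1.0})
        nz = np.nonzero(tr.intensities)[0]
        assert len(nz) == 1
        assert tr.sizes_bp[nz[0]] == locus_a24.product_size_wt

    def test_two_equal_alleles_equal_heights(self, locus_a24):
        wt = locus_a24.product_size_wt
        tr = simulate_electropherogram(locus_a24, {wt: 0.5, wt - 4: 0.5})
        h = dict(zip(tr.sizes_bp, tr.intensities))
        assert h[wt] == h[wt - 4] == 0.5

    def test_stutter_ladder_height_formula(self, locus_a24):
        # height at -k bp is stutter_rate * decay**(k-1) times the main peak
        wt = locus_a24.product_size_wt
        tr = simulate_electropherogram(locus_a24, {wt: 1.0},
                                       stutter_rate=0.1, stutter_decay=0.5)
        h = dict(zip(tr.sizes_bp, tr.intensities))
        assert h[wt - 1] == pytest.approx(0.1 * h[wt])
        assert h[wt - 2] == pytest.approx(0.05 * h[wt])
        assert h[wt + 2] == pytest.approx(0.05 * h[wt])

    def test_fractions_must_sum_to_one(self, locus_a24):
        with pytest.raises(SimulationError, match="sum to 1"):
            simulate_electropherogram(locus_a24, {locus_a24.product_size_wt: 0.9})

    def test_noise_is_seeded_and_non_negative(self, locus_a24):
        args = (locus_a24, {locus_a24.product_size_wt: 1.0}, 0.0, 0.5, 0.02)
        t1 = simulate_electropherogram(*args, seed=4)
        t2 = simulate_electropherogram(*args, seed=4)
        assert np.array_equal(t1.intensities, t2.intensities)
        assert np.all(t1.intensities >= 0)


class TestFixtures:
    def _specs(self, panel):
        return [
            SampleSpec("WT1", "wt_control", depth=30, seed=1),
            SampleSpec("T1", "tumor", depth=30, seed=2,
                       planted_indels={panel[0].locus_id: (-1, 0.4)}),
        ]

    def test_round_trip_and_manifest(self, tmp_path, tiny_panel):
        manifest = write_fixtures(tiny_panel, self._specs(tiny_panel), tmp_path / "fx")
        files = manifest["files"]
        assert {"panel.fasta", "panel.json", "WT1.fastq", "T1.fastq",
                "truth.tsv", "samples.tsv"} <= set(files)
        on_disk = json.load(open(tmp_path / "fx" / "manifest.json"))
        assert on_disk["files"] == files

    def test_truth_table_round_trips_planted_events(self, tmp_path, tiny_panel):
        import pandas as pd

        specs = self._specs(tiny_panel)
        write_fixtures(tiny_panel, specs, tmp_path / "fx")
        truth = pd.read_csv(tmp_path / "fx" / "truth.tsv", sep="\t")
        planted = {
            (s.sample_id, locus, off, vaf)
            for s in specs for locus, (off, vaf) in s.planted_indels.items()
        }
        emitted = {
            (r.sample_id, r.locus_id, r.offset, r.true_vaf)
            for r in truth.itertuples(index=False)
        }
        assert planted == emitted

    def test_rerun_same_seed_byte_identical(self, tmp_path, tiny_panel):
        m1 = write_fixtures(tiny_panel, self._specs(tiny_panel), tmp_path / "a")
        m2 = write_fixtures(tiny_panel, self._specs(tiny_panel), tmp_path / "b")
        assert m1["files"] == m2["files"]

    def test_refuses_overwrite_without_flag(self, tmp_path, tiny_panel):
        write_fixtures(tiny_panel, self._specs(tiny_panel), tmp_path / "fx")
        with pytest.raises(FileExistsError):
            write_fixtures(tiny_panel, self._specs(tiny_panel), tmp_path / "fx")
        write_fixtures(tiny_panel, self._specs(tiny_panel), tmp_path / "fx",
                       overwrite=True)
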
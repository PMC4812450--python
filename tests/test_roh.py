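"""Binning, coverage scaling, ROH calling and diversity outside ROHs."""

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_rohs, random_track
from conftest import make_track
from rohpipe import published, roh, simulate, vcf_io


class TestBinGenome:
    def test_chromosome_tiled_into_expected_bins(self):
        t = vcf_io.VariantTable.from_records([], [], [], [], {"s": []})
        track = roh.bin_genome(t, "s", {"1": 30_000_000})
        assert len(track) == 3000
        assert (track["raw_snp_count"] == 0).all()

    @pytest.mark.parametrize("pos, bin_start", [(1, 0), (10_000, 0), (10_001, 10_000)])
    def test_bin_boundary_convention(self, pos, bin_start):
        t = vcf_io.VariantTable.from_records(["1"], [pos], ["A"], ["C"], {"s": [1]})
        track = roh.bin_genome(t, "s", {"1": 30_000})
        hit = track.loc[track["raw_snp_count"] == 1, "start"]
        assert list(hit) == [bin_start]

    def test_only_heterozygous_sites_counted(self):
        t = vcf_io.VariantTable.from_records(
            ["1"] * 3, [5, 6, 7], ["A"] * 3, ["C"] * 3, {"s": [0, 1, 2]}
        )
        track = roh.bin_genome(t, "s", {"1": 10_000})
        assert track["raw_snp_count"].sum() == 1

    def test_site_beyond_chromosome_end_rejected(self):
        t = vcf_io.VariantTable.from_records(["1"], [20_001], ["A"], ["C"], {"s": [1]})
        with pytest.raises(ValueError, match="beyond chromosome length"):
            roh.bin_genome(t, "s", {"1": 20_000})

    def test_raw_counts_conserve_het_total(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(1, 200_001), size=500, replace=False))
        gt = rng.choice([0, 1, 2], size=500)
        t = vcf_io.VariantTable.from_records(["1"] * 500, pos, ["A"] * 500, ["C"] * 500, {"s": gt})
        track = roh.bin_genome(t, "s", {"1": 200_000})
        assert track["raw_snp_count"].sum() == (gt == 1).sum()


class TestScaleAndFilterBins:
    @pytest.mark.parametrize("raw, covered, expected", [(6, 5000, 12.0), (6, 10_000, 6.0), (0, 7000, 0.0)])
    def test_scaling_to_full_bin_length(self, raw, covered, expected):
        track = make_track([0.0], covered=[covered])
        track["raw_snp_count"] = raw
        out = roh.scale_bins(track)
        assert out["scaled_snp_count"][0] == pytest.approx(expected)

    def test_zero_coverage_bin_dropped(self):
        track = make_track([0.0], covered=[0])
        out = roh.scale_bins(track)
        assert not out["retained"][0]

    @pytest.mark.parametrize("covered, retained", [(999, False), (1000, True), (10_000, True)])
    def test_minimum_covered_sites_cutoff(self, covered, retained):
        track = make_track([1.0], covered=[covered])
        assert bool(roh.filter_bins(track)["retained"][0]) is retained

    def test_sex_chromosome_bins_excluded(self):
        track = make_track([1.0], covered=[10_000], chrom="X")
        assert not roh.filter_bins(track)["retained"][0]
        assert roh.filter_bins(track, sex_chroms=()).loc[0, "retained"]


class TestGenomicAverage:
    @pytest.mark.parametrize("scaled, expected", [([10, 14], 12.0), ([7, 7, 7], 7.0), ([0, 0, 36], 12.0)])
    def test_mean_over_retained_bins(self, scaled, expected):
        assert roh.genomic_average(make_track(scaled)) == pytest.approx(expected)

    def test_error_without_retained_bins(self):
        track = make_track([1.0], retained=[False])
        with pytest.raises(ValueError, match="no retained bins"):
            roh.genomic_average(track)


class TestCallRohs:
    def test_twenty_low_bins_make_one_roh(self):
        track = make_track([0.0] * 20 + [12.0] * 10)
        rohs = roh.call_rohs(track, genomic_avg=12.0)
        assert len(rohs) == 1
        assert rohs.loc[0, "length"] == 200_000
        assert rohs.loc[0, "n_bins"] == 20

    def test_nineteen_bins_are_not_enough(self):
        track = make_track([0.0] * 19 + [12.0] * 10)
        assert len(roh.call_rohs(track, genomic_avg=12.0)) == 0

    def test_cutoff_is_strictly_below(self):
        # avg 12 -> cutoff 0.33*12 = 3.96
        at_cutoff = make_track([3.96] * 25)
        below = make_track([3.95] * 25)
        assert len(roh.call_rohs(at_cutoff, genomic_avg=12.0)) == 0
        assert len(roh.call_rohs(below, genomic_avg=12.0)) == 1

    def test_non_retained_bin_terminates_run(self):
        retained = [True] * 15 + [False] + [True] * 15
        track = make_track([0.0] * 31, retained=retained)
        assert len(roh.call_rohs(track, genomic_avg=12.0)) == 0

    def test_gap_tolerance_merges_runs(self):
        scaled = [0.0] * 15 + [12.0] + [0.0] * 15
        track = make_track(scaled)
        assert len(roh.call_rohs(track, genomic_avg=12.0)) == 0
        merged = roh.call_rohs(track, genomic_avg=12.0, max_gap_bins=1)
        assert len(merged) == 1
        assert merged.loc[0, "n_bins"] == 30  # qualifying bins only
        assert merged.loc[0, "length"] == 310_000

    def test_agrees_with_brute_force_scan(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            track = random_track(rng, int(rng.integers(40, 200)))
            avg = roh.genomic_average(track)
            fast = roh.call_rohs(track, avg)
            slow = brute_force_rohs(track, avg)
            pd.testing.assert_frame_equal(fast.reset_index(drop=True), slow.reset_index(drop=True))

    def test_monotonic_in_frac_and_min_bins(self):
        rng = np.random.default_rng(42)
        track = random_track(rng, 150)
        avg = roh.genomic_average(track)
        for lo, hi in [(0.2, 0.33), (0.1, 0.2)]:
            n_lo = roh.call_rohs(track, avg, frac=lo)["n_bins"].sum()
            n_hi = roh.call_rohs(track, avg, frac=hi)["n_bins"].sum()
            assert n_lo <= n_hi
        for small, big in [(10, 20), (20, 40)]:
            assert len(roh.call_rohs(track, avg, min_bins=big)) <= len(
                roh.call_rohs(track, avg, min_bins=small)
            )


class TestClassifyLengths:
    def test_half_open_length_categories(self):
        rohs = pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "start": [0, 0],
                "end": [300_000, 500_000],
                "n_bins": [30, 50],
                "length": [300_000, 500_000],
            }
        )
        out = roh.classify_lengths(rohs)
        assert out.loc["0.2-0.5", "n_rohs"] == 1  # 0.3 Mb
        assert out.loc["0.5-1", "n_rohs"] == 1  # exactly 0.5 Mb moves up

    def test_empty_input_gives_zero_everywhere(self):
        out = roh.classify_lengths(pd.DataFrame(columns=roh.ROH_COLUMNS))
        assert (out["n_rohs"] == 0).all() and (out["total_bp"] == 0).all()

    def test_too_short_roh_rejected(self):
        rohs = pd.DataFrame(
            {"chrom": ["1"], "start": [0], "end": [100_000], "n_bins": [10], "length": [100_000]}
        )
        with pytest.raises(ValueError, match="smallest category edge"):
            roh.classify_lengths(rohs)


class TestDiversityOutside:
    def test_without_rohs_equals_genomic_average(self):
        track = make_track([10, 14, 12])
        empty = pd.DataFrame(columns=roh.ROH_COLUMNS)
        assert roh.diversity_outside(track, empty) == roh.genomic_average(track)

    def test_roh_bins_excluded_from_pi(self):
        track = make_track([0.0] * 20 + [12.0, 12.0])
        rohs = roh.call_rohs(track, genomic_avg=roh.genomic_average(track))
        assert len(rohs) == 1
        assert roh.diversity_outside(track, rohs) == pytest.approx(12.0)

    def test_all_bins_in_roh_is_an_error(self):
        track = make_track([0.0] * 25)
        rohs = roh.call_rohs(track, genomic_avg=12.0)
        with pytest.raises(ValueError, match="inside a ROH"):
            roh.diversity_outside(track, rohs)

    def test_recovers_simulated_rate(self):
        cfg = simulate.SimConfig(chrom_lengths={"1": 30_000_000}, seed=9)
        vt, cov, _ = simulate.simulate_individual(cfg)
        f = vcf_io.filter_depth(vt, vcf_io.DepthFilterConfig(mean_depths={"indiv1": cfg.mean_depth}))
        track = roh.filter_bins(roh.scale_bins(roh.bin_genome(f, "indiv1", cfg.chrom_lengths, cov)))
        rohs = roh.call_rohs(track)
        assert roh.diversity_outside(track, rohs) == pytest.approx(12.0, rel=0.05)


class TestSummaries:
    def test_cohort_and_island_means_match_reported_values(self):
        df = published.CEBIFRONS.rename(columns={"sample": "sample"})
        groups = dict(zip(df["sample"], df["island"]))
        out = roh.summarize_cohort(df, groups)
        assert roh.round_half_away(out.loc["all", "n_rohs_mean"]) == 117
        assert roh.round_half_away(out.loc["panay", "n_rohs_mean"]) == 142
        assert roh.round_half_away(out.loc["negros", "n_rohs_mean"]) == 55
        assert roh.round_half_away(out.loc["all", "n_rohs_sd"]) == 51

    def test_single_sample_group_has_no_sd(self):
        df = pd.DataFrame({"sample": ["a", "b"], "n_rohs": [10, 20], "mean_roh_length_kb": [1.0, 2.0], "pi": [1.0, 2.0]})
        out = roh.summarize_cohort(df, {"a": "g1", "b": "g2"})
        assert np.isnan(out.loc["g1", "n_rohs_sd"])

    def test_unmapped_sample_is_an_error(self):
        df = pd.DataFrame({"sample": ["a"], "n_rohs": [1], "mean_roh_length_kb": [1.0], "pi": [1.0]})
        with pytest.raises(ValueError, match="without a group"):
            roh.summarize_cohort(df, {})

    def test_summarize_sample_fractions(self):
        track = make_track([0.0] * 30 + [12.0] * 70)
        rohs = roh.call_rohs(track, genomic_avg=roh.genomic_average(track))
        s = roh.summarize_sample("s", track, rohs)
        assert s.n_rohs == 1
        assert s.mean_roh_length_kb == pytest.approx(300.0)
        assert s.genome_fraction_in_roh["0.2-0.5"] == pytest.approx(0.3)

    @pytest.mark.parametrize("x, expected", [(116.857, 117), (54.5, 55), (-2.5, -3), (2.45, 2.5)])
    def test_round_half_away(self, x, expected):
        nd = 1 if expected != int(expected) else 0
        assert roh.round_half_away(x, nd) == expected
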
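import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methylrescue import (
    SignalTrack, compare_enrichment, load_signal_track, scaled_region_profile,
    stratified_enrichment, tss_meta_profile, write_signal_track,
)


def constant_track(value=5.0, bin_size=10, nbins=2_000, chroms=("chr1",)):
    return SignalTrack("mark", bin_size, {c: np.full(nbins, value) for c in chroms})


def tss_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss"])


class TestLoadTrack:
    def test_empty_file_gives_empty_track(self, tmp_path):
        p = tmp_path / "empty.bedGraph"
        p.write_text("")
        assert load_signal_track(p).values == {}

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        track = SignalTrack("H3K4me3", 10, {"chr1": rng.uniform(0, 3, 100), "chr2": rng.uniform(0, 3, 50)})
        p = tmp_path / "t.bedGraph"
        write_signal_track(track, p)
        back = load_signal_track(p, "H3K4me3")
        assert back.bin_size == 10
        for c in track.values:
            np.testing.assert_allclose(back.values[c], track.values[c], atol=5e-7)

    def test_overlapping_intervals_rejected(self, tmp_path):
        p = tmp_path / "bad.bedGraph"
        p.write_text("chr1\t0\t10\t1.0\nchr1\t0\t10\t2.0\n")
        with pytest.raises(ValueError, match="overlap"):
            load_signal_track(p)

    def test_ragged_bins_rejected(self, tmp_path):
        p = tmp_path / "bad.bedGraph"
        p.write_text("chr1\t0\t10\t1.0\nchr1\t10\t25\t2.0\n")
        with pytest.raises(ValueError, match="fixed-width"):
            load_signal_track(p)


class TestTssProfile:
    def test_uniform_signal_gives_flat_profile(self):
        track = constant_track(5.0)
        mp = tss_meta_profile(track, tss_table([("g1", "chr1", "+", 10_000)]), 2_000, 100)
        np.testing.assert_allclose(mp.mean, 5.0)
        assert len(mp.bin_coords) == 40

    def test_strand_flip_mirrors_profile(self):
        rng = np.random.default_rng(1)
        track = SignalTrack("m", 10, {"chr1": rng.uniform(0, 4, 4_000)})
        plus = tss_meta_profile(track, tss_table([("g", "chr1", "+", 20_000)]), 1_000, 50)
        minus = tss_meta_profile(track, tss_table([("g", "chr1", "-", 20_000)]), 1_000, 50)
        np.testing.assert_allclose(plus.mean, minus.mean[::-1])

    def test_half_window_must_be_multiple_of_bin_size(self):
        with pytest.raises(ValueError):
            tss_meta_profile(constant_track(), tss_table([("g", "chr1", "+", 500)]), 1_001, 10)

    def test_matches_brute_force_bin_average_on_methylation(self):
        values = pd.DataFrame({"chrom": "chr1",
                               "pos": [95, 105, 120, 130, 145, 260],
                               "value": [10.0, 20.0, 30.0, 40.0, 50.0, 90.0]})
        mp = tss_meta_profile(values, tss_table([("g", "chr1", "+", 100)]), 100, 50)
        # bins: [0,50), [50,100), [100,150), [150,200)
        expected = [np.nan, 10.0, np.mean([20, 30, 40, 50]), np.nan]
        np.testing.assert_allclose(mp.mean, expected)
        np.testing.assert_array_equal(mp.n, [0, 1, 1, 0])

    def test_multi_tss_mean_and_sem(self):
        rng = np.random.default_rng(2)
        arr = rng.uniform(0, 2, 3_000)
        track = SignalTrack("m", 10, {"chr1": arr})
        tsss = tss_table([(f"g{i}", "chr1", "+", p) for i, p in enumerate((5_000, 9_000, 14_000))])
        mp = tss_meta_profile(track, tsss, 500, 100)
        # brute force per bin across the three windows
        for b in range(10):
            per_region = []
            for p in (5_000, 9_000, 14_000):
                s = p - 500 + b * 100
                per_region.append(arr[s // 10: (s + 100) // 10].mean())
            assert mp.mean[b] == pytest.approx(np.mean(per_region))
            assert mp.sem[b] == pytest.approx(np.std(per_region, ddof=1) / np.sqrt(3))


class TestScaledProfile:
    def regions(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def test_constant_signal_constant_profile(self):
        mp = scaled_region_profile(constant_track(3.0), self.regions([("chr1", 2_000, 3_234)]))
        np.testing.assert_allclose(mp.mean, 3.0)
        assert len(mp.bin_coords) == 100 + 2 * 10

    def test_thousand_bp_region_scaling_is_identity(self):
        rng = np.random.default_rng(3)
        arr = rng.uniform(0, 5, 1_000)
        track = SignalTrack("m", 10, {"chr1": arr})
        mp = scaled_region_profile(track, self.regions([("chr1", 4_000, 5_000)]),
                                   body_bins=100, bin_size=10, flank=100)
        np.testing.assert_allclose(mp.mean[10:110], arr[400:500])

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_interpolation_oracle_on_random_regions(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.uniform(0, 5, 5_000)
        track = SignalTrack("m", 10, {"chr1": arr})
        start = int(rng.integers(1_000, 20_000))
        length = int(rng.integers(300, 4_000))
        body_bins, bin_size, flank = 20, 10, 50
        mp = scaled_region_profile(track, self.regions([("chr1", start, start + length)]),
                                   body_bins=body_bins, bin_size=bin_size, flank=flank)
        for b in range(body_bins):
            lo = start + length * b / body_bins
            hi = start + length * (b + 1) / body_bins
            # bp-weighted mean of track bins over [lo, hi)
            total = weight = 0.0
            for k in range(int(lo // 10), int(np.ceil(hi / 10))):
                ov = min(hi, (k + 1) * 10) - max(lo, k * 10)
                if ov > 0 and k < len(arr):
                    total += arr[k] * ov
                    weight += ov
            assert mp.mean[flank // bin_size + b] == pytest.approx(total / weight)

    def test_profile_invariant_under_region_order(self):
        rng = np.random.default_rng(4)
        track = SignalTrack("m", 10, {"chr1": rng.uniform(0, 5, 5_000)})
        regs = self.regions([("chr1", 1_000, 1_800), ("chr1", 9_000, 9_700), ("chr1", 20_000, 21_000)])
        a = scaled_region_profile(track, regs)
        b = scaled_region_profile(track, regs.iloc[::-1].reset_index(drop=True))
        np.testing.assert_allclose(a.mean, b.mean)

    def test_sem_decreases_with_region_count_on_homogeneous_regions(self):
        rng = np.random.default_rng(5)
        track = SignalTrack("m", 10, {"chr1": 1.0 + rng.normal(0, 0.2, 100_000)})
        regs = self.regions([("chr1", 1_000 + 2_000 * i, 2_000 + 2_000 * i) for i in range(40)])
        small = scaled_region_profile(track, regs.iloc[:8])
        large = scaled_region_profile(track, regs)
        assert np.nanmean(large.sem) < np.nanmean(small.sem)


class TestEnrichment:
    def bumped_track(self, regions, fold, seed=0, nbins=50_000):
        rng = np.random.default_rng(seed)
        arr = 1.0 + rng.normal(0, 0.1, nbins)
        for _, row in regions.iterrows():
            arr[row.start // 10: row.end // 10] *= fold
        return SignalTrack("m", 10, {"chr1": np.clip(arr, 0.01, None)})

    def region_set(self, n, offset=0):
        return pd.DataFrame({"chrom": "chr1",
                             "start": [offset + 5_000 * i for i in range(1, n + 1)],
                             "end": [offset + 5_000 * i + 800 for i in range(1, n + 1)]})

    def test_identical_sets_give_p_near_one(self):
        regs = self.region_set(10)
        track = self.bumped_track(regs, 1.0)
        res = compare_enrichment(track, regs, regs.copy())
        assert res.p_value > 0.9

    def test_planted_three_fold_difference_detected(self):
        a = self.region_set(50, offset=0)
        b = self.region_set(50, offset=1_500)
        track = self.bumped_track(a, 3.0, seed=1, nbins=30_000)
        res = compare_enrichment(track, a, b)
        assert res.p_value < 0.05
        assert res.statistic > 0

    def test_swapping_sets_preserves_p(self):
        a = self.region_set(20)
        b = self.region_set(20, offset=2_000)
        track = self.bumped_track(a, 2.0, seed=2)
        r1 = compare_enrichment(track, a, b)
        r2 = compare_enrichment(track, b, a)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.statistic == pytest.approx(-r2.statistic)

    def test_stratified_reports_no_test_for_small_strata(self):
        a = self.region_set(6)
        b = self.region_set(6, offset=2_000)
        a["exon"] = [True] * 5 + [False]
        b["exon"] = [True, False, False, False, False, False]
        a["CGI"] = False
        b["CGI"] = False
        track = self.bumped_track(a, 2.0, seed=3)
        out = stratified_enrichment(track, a, b, kinds=["exon", "CGI"]).set_index("kind")
        assert not bool(out.loc["exon", "tested"]) or out.loc["exon", "n_b"] >= 2
        assert not bool(out.loc["CGI", "tested"])

    def test_stratum_means_match_direct_recomputation(self):
        from methylrescue.profiles import region_means
        a = self.region_set(8)
        b = self.region_set(8, offset=2_200)
        a["exon"] = True
        b["exon"] = True
        track = self.bumped_track(a, 2.0, seed=4)
        out = stratified_enrichment(track, a, b, kinds=["exon"]).iloc[0]
        assert out.mean_a == pytest.approx(np.nanmean(region_means(track, a)))
        assert out.mean_b == pytest.approx(np.nanmean(region_means(track, b)))
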
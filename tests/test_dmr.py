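import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from methylrescue import Thresholds, call_dmcs, dmr_cpg_matrix, pairwise_site_correlation, segment_dmrs
from conftest import two_group_cohort


def brute_force_dmrs(cohort, dmcs, reference, test, th):
    """Independent segmentation oracle: enumerate all maximal qualifying runs
    over the common sites, testing each with scipy's Mann-Whitney U."""
    sites = cohort.sites
    dmc_map = {}
    for row in dmcs.itertuples(index=False):
        dmc_map[(row.chrom, row.pos)] = row.delta

    idx = list(sites.itertuples(index=False))
    n = len(idx)

    def is_dmc(i):
        return (idx[i].chrom, idx[i].pos) in dmc_map

    def delta(i):
        return dmc_map[(idx[i].chrom, idx[i].pos)]

    def compatible(i, j):
        """site j can follow site i inside one run (j = i+1 in site order)"""
        if idx[i].chrom != idx[j].chrom:
            return False
        if not (is_dmc(i) and is_dmc(j)):
            return False
        if (delta(i) > 0) != (delta(j) > 0):
            return False
        return idx[j].pos - idx[i].pos <= th.max_gap

    runs = []
    i = 0
    while i < n:
        if not is_dmc(i):
            i += 1
            continue
        j = i
        while j + 1 < n and compatible(j, j + 1):
            if th.max_span is not None and idx[j + 1].pos + 1 - idx[i].pos > th.max_span:
                break
            j += 1
        runs.append(list(range(i, j + 1)))
        i = j + 1
    out = []
    for run in runs:
        if len(run) < th.min_dmcs:
            continue
        deltas = [delta(k) for k in run]
        if abs(np.mean(deltas)) < th.min_diff:
            continue
        xs = cohort.per_sample_percent[test].to_numpy()[run].ravel()
        ys = cohort.per_sample_percent[reference].to_numpy()[run].ravel()
        if np.ptp(np.concatenate([xs, ys])) == 0:
            continue
        p = sps.mannwhitneyu(xs, ys, alternative="two-sided").pvalue
        if not p < th.alpha:
            continue
        out.append((idx[run[0]].chrom, idx[run[0]].pos, idx[run[-1]].pos + 1, len(run)))
    return out


class TestCallDmcs:
    def test_published_threshold_example(self):
        cohort = two_group_cohort([100], [80.0], [45.0], jitter=0)
        dmcs = call_dmcs(cohort, "WT", "KO")
        assert len(dmcs) == 1
        assert dmcs.iloc[0].delta == pytest.approx(-35.0)
        assert dmcs.iloc[0].direction == "hypo"

    def test_identical_groups_give_no_dmcs(self):
        cohort = two_group_cohort([10, 20, 30], [50, 60, 70], [50, 60, 70], jitter=0)
        assert len(call_dmcs(cohort, "WT", "KO")) == 0

    def test_threshold_is_inclusive_at_exactly_thirty(self):
        # coverage 200 gives exact percent resolution of 0.5 points
        cohort = two_group_cohort([10, 20], [80.0, 80.0], [50.0, 50.5], coverage=200, jitter=0)
        dmcs = call_dmcs(cohort, "WT", "KO")
        assert dmcs["pos"].tolist() == [10]  # delta -30.0 in, -29.5 out

    def test_unknown_group_rejected(self):
        cohort = two_group_cohort([10], [50.0], [50.0])
        with pytest.raises(KeyError):
            call_dmcs(cohort, "WT", "XX")


class TestSegmentation:
    def test_three_hypo_dmcs_within_gap_form_one_dmr(self):
        cohort = two_group_cohort([0, 40, 80], [80, 82, 81], [45, 42, 48], seed=1)
        th = Thresholds()
        dmcs = call_dmcs(cohort, "WT", "KO", th)
        dmrs = segment_dmrs(dmcs, cohort, "WT", "KO", th)
        assert len(dmrs) == 1
        d = dmrs.iloc[0]
        assert (d.start, d.end, d.n_dmcs, d.direction) == (0, 81, 3, "hypo")
        assert d.p_value < 0.05

    def test_two_dmcs_below_minimum_yield_nothing(self):
        cohort = two_group_cohort([0, 40], [80, 82], [45, 42], seed=1)
        dmcs = call_dmcs(cohort, "WT", "KO")
        assert len(segment_dmrs(dmcs, cohort, "WT", "KO")) == 0

    def test_direction_change_breaks_run(self):
        cohort = two_group_cohort([0, 40, 80], [80, 20, 81], [45, 60, 48], seed=1)
        dmcs = call_dmcs(cohort, "WT", "KO")
        assert len(dmcs) == 3
        assert len(segment_dmrs(dmcs, cohort, "WT", "KO")) == 0

    def test_intervening_non_dmc_breaks_run(self):
        # five sites, middle one unchanged: no run of three consecutive DMCs
        cohort = two_group_cohort([0, 25, 50, 75, 100],
                                  [80, 81, 80, 82, 81], [45, 42, 80, 44, 46], seed=1)
        dmcs = call_dmcs(cohort, "WT", "KO")
        assert len(dmcs) == 4
        assert len(segment_dmrs(dmcs, cohort, "WT", "KO")) == 0

    def test_gap_above_max_breaks_run(self):
        cohort = two_group_cohort([0, 40, 120], [80, 82, 81], [45, 42, 48], seed=1)
        dmcs = call_dmcs(cohort, "WT", "KO")
        th = Thresholds(max_gap=50)
        assert len(segment_dmrs(dmcs, cohort, "WT", "KO", th)) == 0
        th_wide = Thresholds(max_gap=100)
        assert len(segment_dmrs(dmcs, cohort, "WT", "KO", th_wide)) == 1

    def test_max_span_caps_region_length(self):
        positions = [0, 40, 80, 120, 160, 200]
        cohort = two_group_cohort(positions, [80] * 6, [40] * 6, seed=1)
        dmcs = call_dmcs(cohort, "WT", "KO")
        unlimited = segment_dmrs(dmcs, cohort, "WT", "KO", Thresholds())
        assert len(unlimited) == 1 and unlimited.iloc[0].n_dmcs == 6
        capped = segment_dmrs(dmcs, cohort, "WT", "KO", Thresholds(max_span=130))
        # the second fragment (160, 200) has only two DMCs and is dropped
        assert len(capped) == 1
        assert capped.iloc[0].n_dmcs == 4
        assert capped.iloc[0].end - capped.iloc[0].start <= 130

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_enumeration_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        positions = np.sort(rng.choice(8_000, size=n, replace=False))
        ref = rng.uniform(0, 100, n)
        # test percents: correlated with ref but with frequent big drops/jumps
        shift = rng.choice([0, -40, -50, 40], size=n, p=[0.45, 0.25, 0.2, 0.1])
        test = np.clip(ref + shift + rng.normal(0, 4, n), 0, 100)
        cohort = two_group_cohort(positions, ref, test, coverage=50, jitter=2.0,
                                  seed=int(rng.integers(1 << 30)))
        th = Thresholds(max_gap=int(rng.choice([50, 100])),
                        max_span=int(rng.choice([200, 10_000])))
        dmcs = call_dmcs(cohort, "WT", "KO", th)
        got = segment_dmrs(dmcs, cohort, "WT", "KO", th)
        expected = brute_force_dmrs(cohort, dmcs, "WT", "KO", th)
        got_tuples = [(r.chrom, r.start, r.end, r.n_dmcs) for r in got.itertuples(index=False)]
        assert got_tuples == expected

    def test_dmrs_disjoint_sorted_and_made_of_dmcs(self, tiny_cohort):
        th = Thresholds()
        dmcs = call_dmcs(tiny_cohort, "WT", "KO", th)
        dmrs = segment_dmrs(dmcs, tiny_cohort, "WT", "KO", th)
        assert len(dmrs) > 0
        dmc_set = {(r.chrom, r.pos) for r in dmcs.itertuples(index=False)}
        prev_end = {}
        for r in dmrs.itertuples(index=False):
            assert all((r.chrom, p) in dmc_set for p in r.members)
            assert r.start >= prev_end.get(r.chrom, -1)
            prev_end[r.chrom] = r.end
            assert abs(r.mean_delta) >= th.min_diff
            assert r.p_value < th.alpha
            assert r.n_dmcs >= th.min_dmcs

    def test_raising_min_dmcs_never_increases_dmr_count(self, tiny_cohort):
        th0 = Thresholds()
        dmcs = call_dmcs(tiny_cohort, "WT", "KO", th0)
        counts = [len(segment_dmrs(dmcs, tiny_cohort, "WT", "KO", Thresholds(min_dmcs=v)))
                  for v in (2, 3, 5)]
        assert counts == sorted(counts, reverse=True)

    def test_raising_min_diff_never_increases_dmc_count(self, tiny_cohort):
        # NOTE: the analogous claim for DMR counts is false under the strict
        # run-break rule: raising min_diff can turn one long run into two
        # qualifying shorter runs. DMC counts are strictly monotone.
        counts = [len(call_dmcs(tiny_cohort, "WT", "KO", Thresholds(min_diff=v)))
                  for v in (20.0, 30.0, 45.0)]
        assert counts == sorted(counts, reverse=True)

    def test_raising_min_diff_shrinks_dmc_set_not_just_count(self, tiny_cohort):
        loose = call_dmcs(tiny_cohort, "WT", "KO", Thresholds(min_diff=30.0))
        strict = call_dmcs(tiny_cohort, "WT", "KO", Thresholds(min_diff=45.0))
        loose_set = set(zip(loose["chrom"], loose["pos"]))
        strict_set = set(zip(strict["chrom"], strict["pos"]))
        assert strict_set <= loose_set


class TestPlantedRecovery:
    def test_planted_regions_recovered_with_tight_boundaries(self):
        """Planted 50-point effects at 30x over >= 3 CpGs are recovered with
        boundary error of at most one CpG in at least 95% of 200 regions."""
        from methylrescue import SimConfig, build_cohort, simulate_methylation

        cfg = SimConfig(seed=5, n_chromosomes=2, chrom_length=1_200_000, n_genes=10,
                        n_background_cpgs=500, n_weak=200, n_strong=0, n_ci_only=0,
                        n_gain=0, n_loss=0, group_counts=(0, 0, 0),
                        n_denovo_promoters=0, n_denovo_down=0,
                        n_genes_expression=100, n_up_genes=0, n_down_genes=0)
        profiles, truth, genome = simulate_methylation(cfg)
        stage = cfg.late_stage
        cohort = build_cohort({g: [profiles[f"{g}_{stage}_rep{i}"] for i in (1, 2)]
                               for g in ("WT", "KO")}, min_cov=15)
        th = Thresholds()
        dmcs = call_dmcs(cohort, "WT", "KO", th)
        dmrs = segment_dmrs(dmcs, cohort, "WT", "KO", th)
        planted = truth.regions_of("weak")
        spacing = cfg.cpg_spacing
        hits = 0
        for region in planted.itertuples(index=False):
            sub = dmrs[(dmrs["chrom"] == region.chrom)
                       & (dmrs["start"] < region.end) & (dmrs["end"] > region.start)]
            if len(sub) != 1:
                continue
            d = sub.iloc[0]
            if abs(d.start - region.start) <= spacing and abs(d.end - region.end) <= spacing:
                hits += 1
        assert hits >= 0.95 * len(planted)


class TestCorrelationAndMatrix:
    def test_group_with_itself_is_one(self, tiny_cohort):
        assert pairwise_site_correlation(tiny_cohort, "WT", "WT") == pytest.approx(1.0)

    def test_anticorrelated_toy_table(self):
        cohort = two_group_cohort([0, 10, 20, 30], [10, 40, 60, 90], [90, 60, 40, 10], jitter=0)
        assert pairwise_site_correlation(cohort, "WT", "KO") == pytest.approx(-1.0)

    def test_dmr_cpg_matrix_rows_are_distinct_member_union(self, tiny_cohort):
        th = Thresholds()
        dmcs = call_dmcs(tiny_cohort, "WT", "KO", th)
        dmrs = segment_dmrs(dmcs, tiny_cohort, "WT", "KO", th)
        m = dmr_cpg_matrix(tiny_cohort, dmrs)
        union = {(r.chrom, p) for r in dmrs.itertuples(index=False) for p in r.members}
        assert len(m) == len(union)
        assert ((m.values >= 0) & (m.values <= 100)).all()

    def test_empty_dmr_list_gives_empty_matrix(self, tiny_cohort):
        assert len(dmr_cpg_matrix(tiny_cohort, pd.DataFrame(columns=["chrom", "members"]))) == 0
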
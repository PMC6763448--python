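import numpy as np
import pandas as pd
import pytest

from methylrescue import SampleProfile, SimConfig, build_cohort, simulate_methylation


def make_profile(sample_id, genotype, stage, records):
    """records: iterable of (chrom, pos, meth, unmeth)."""
    df = pd.DataFrame(records, columns=["chrom", "pos", "meth", "unmeth"])
    return SampleProfile(sample_id, genotype, stage, df)


def profile_from_percents(sample_id, genotype, stage, positions, percents, coverage=20, chrom="chr1"):
    """Profile with counts chosen so the per-site percent equals ``percents``."""
    recs = []
    for pos, pct in zip(positions, percents):
        meth = int(round(coverage * pct / 100.0))
        recs.append((chrom, int(pos), meth, coverage - meth))
    return make_profile(sample_id, genotype, stage, recs)


def two_group_cohort(positions, ref_percents, test_percents, coverage=20, min_cov=15,
                     jitter=2.0, seed=0):
    """WT/KO cohort with two replicates per group.

    Replicate percents are the group value +- ``jitter`` so the rank test
    sees separated but non-identical samples.
    """
    rng = np.random.default_rng(seed)
    groups = {}
    for label, pcts in (("WT", ref_percents), ("KO", test_percents)):
        reps = []
        for r in (1, 2):
            shifted = np.clip(np.asarray(pcts, dtype=float) + rng.uniform(-jitter, jitter, len(pcts)), 0, 100)
            reps.append(profile_from_percents(f"{label}_rep{r}", label, "E11.5",
                                              positions, shifted, coverage=coverage))
        groups[label] = reps
    return build_cohort(groups, min_cov=min_cov)


@pytest.fixture(scope="session")
def tiny_config():
    """Small planted study reused by several suites (seconds to simulate)."""
    return SimConfig(
        seed=11, n_chromosomes=2, chrom_length=400_000, n_genes=20,
        n_background_cpgs=400, n_weak=30, n_strong=6, n_ci_only=4,
        n_gain=8, n_loss=6, n_gain_dependent=4, n_gain_catalytic=2,
        n_denovo_promoters=4, n_denovo_down=2, group_counts=(5, 6, 4),
        n_genes_expression=300, n_up_genes=10, n_down_genes=15,
        n_enhancers=10, n_repeats=20,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    profiles, truth, genome = simulate_methylation(tiny_config)
    return profiles, truth, genome


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config, tiny_study):
    profiles, _, _ = tiny_study
    stage = tiny_config.late_stage
    return build_cohort(
        {g: [profiles[f"{g}_{stage}_rep{i}"] for i in (1, 2)] for g in ("WT", "KO", "CI")},
        min_cov=15,
    )
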
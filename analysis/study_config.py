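"""Shared configuration for the numbered analysis drivers.

The study design is the full published scale: WT / Dnmt3b-null (KO) /
catalytically-inactive (CI) embryos, 2 RRBS replicates each at ~30x, with
4133 weak, 205 strong and 110 CI-only regions, 133 temporal gains and 196
losses, the 22+9 ICR panel, and 12,000-gene expression (3 replicates per
genotype). Every driver re-derives its inputs deterministically from this
one config, so the scripts can run independently and in any order.
"""

from functools import lru_cache
from pathlib import Path

from methylrescue import SimConfig, Thresholds, build_cohort, simulate_methylation

STUDY = SimConfig(seed=1)
THRESHOLDS = Thresholds()

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "analysis"


@lru_cache(maxsize=1)
def study_data():
    """(profiles, truth, genome) for the full-scale synthetic study."""
    return simulate_methylation(STUDY)


@lru_cache(maxsize=1)
def late_cohort():
    profiles, _, _ = study_data()
    stage = STUDY.late_stage
    return build_cohort(
        {g: [profiles[f"{g}_{stage}_rep{i}"] for i in (1, 2)] for g in ("WT", "KO", "CI")},
        min_cov=THRESHOLDS.min_cov,
    )


def ensure_dirs():
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
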
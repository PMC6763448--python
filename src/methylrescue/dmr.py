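"""DMC calling and DMR segmentation.

A differentially methylated cytosine (DMC) is a common site whose pooled
test-minus-reference percent difference is at least ``min_diff`` points
(inclusive). DMRs are maximal runs of same-direction DMCs among the covered
common CpGs: an intervening covered non-DMC CpG breaks a run (strictest
reading of "consecutive"; relaxable via ``allow_skip``), as do gaps above
``max_gap`` bp, chromosome boundaries, and an optional ``max_span`` cap on
region length. A run is kept as a DMR when it has at least ``min_dmcs``
members, |mean of member deltas| >= ``min_diff``, and a two-sided
Mann-Whitney U test on the per-sample per-CpG percents of the two groups
within the run gives p < ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CohortTable
from .stats import mann_whitney_u, pearson_r

DMR_COLUMNS = ["chrom", "start", "end", "n_dmcs", "mean_delta", "direction", "p_value", "members"]


@dataclass
class Thresholds:
    """Calling thresholds; defaults are the embryo-mode values.

    Cell-line mode uses min_cov=10 and max_gap=100. ``max_span`` optionally
    caps total region length in bp (setting it to 200 reproduces the looser
    dialect of the rule that bounds the whole region instead of each gap);
    ``allow_skip`` > 0 lets a run jump over that many intervening non-DMC
    common CpGs.
    """

    min_cov: int = 15
    min_diff: float = 30.0
    min_dmcs: int = 3
    max_gap: int = 50
    max_span: int | None = None
    alpha: float = 0.05
    allow_skip: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.min_diff <= 100):
            raise ValueError("min_diff must be in (0, 100]")
        if self.min_dmcs < 2:
            raise ValueError("min_dmcs must be >= 2")
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")

    @classmethod
    def cell_line(cls, **kw) -> "Thresholds":
        kw.setdefault("min_cov", 10)
        kw.setdefault("max_gap", 100)
        return cls(**kw)


def _require_groups(cohort: CohortTable, *labels: str) -> None:
    for label in labels:
        if label not in cohort.group_percent.columns:
            raise KeyError(f"group {label!r} not in cohort (have {list(cohort.group_percent.columns)})")


def call_dmcs(cohort: CohortTable, reference: str, test: str, th: Thresholds | None = None) -> pd.DataFrame:
    """One row per common site with |pooled test - pooled reference| >= min_diff.

    Delta sign is test minus reference; direction is hyper for positive delta,
    hypo for negative.
    """
    th = th or Thresholds()
    _require_groups(cohort, reference, test)
    delta = cohort.group_percent[test] - cohort.group_percent[reference]
    mask = delta.abs() >= th.min_diff
    out = cohort.sites.loc[mask.values, ["chrom", "pos"]].copy()
    out["delta"] = delta[mask.values].values
    out["direction"] = np.where(out["delta"] > 0, "hyper", "hypo")
    return out.reset_index(drop=True)


def _empty_dmrs() -> pd.DataFrame:
    return pd.DataFrame(columns=DMR_COLUMNS)


def segment_dmrs(
    dmcs: pd.DataFrame,
    cohort: CohortTable,
    reference: str,
    test: str,
    th: Thresholds | None = None,
) -> pd.DataFrame:
    """Segment DMCs into DMRs (see module docstring for the rule).

    Returns a sorted, disjoint DMR table; ``members`` holds the member DMC
    positions, the interval is [first member, last member + 1).
    """
    th = th or Thresholds()
    _require_groups(cohort, reference, test)
    if len(dmcs) == 0:
        return _empty_dmrs()

    site_index = cohort.site_index()
    dmc_index = pd.MultiIndex.from_frame(dmcs[["chrom", "pos"]])
    if not dmc_index.isin(site_index).all():
        raise ValueError("DMC at a position missing from the cohort's common sites")

    chroms = cohort.sites["chrom"].to_numpy()
    positions = cohort.sites["pos"].to_numpy()
    is_dmc = np.zeros(len(positions), dtype=bool)
    deltas = np.full(len(positions), np.nan)
    locs = site_index.get_indexer(dmc_index)
    is_dmc[locs] = True
    deltas[locs] = dmcs["delta"].to_numpy()

    ref_pct = cohort.per_sample_percent[reference].to_numpy()
    test_pct = cohort.per_sample_percent[test].to_numpy()

    dmrs: list[dict] = []

    def flush(run: list[int]) -> None:
        if len(run) < th.min_dmcs:
            return
        run_deltas = deltas[run]
        mean_delta = float(run_deltas.mean())
        if abs(mean_delta) < th.min_diff:
            return
        xs = test_pct[run].ravel()
        ys = ref_pct[run].ravel()
        res = mann_whitney_u(xs[~np.isnan(xs)], ys[~np.isnan(ys)])
        if not (res.p_value < th.alpha):
            return
        member_pos = positions[run]
        dmrs.append(
            {
                "chrom": chroms[run[0]],
                "start": int(member_pos[0]),
                "end": int(member_pos[-1]) + 1,
                "n_dmcs": len(run),
                "mean_delta": mean_delta,
                "direction": "hyper" if mean_delta > 0 else "hypo",
                "p_value": res.p_value,
                "members": list(map(int, member_pos)),
            }
        )

    run: list[int] = []
    skipped = 0
    for i in range(len(positions)):
        if not is_dmc[i]:
            if run:
                if skipped < th.allow_skip and chroms[i] == chroms[run[-1]]:
                    skipped += 1
                else:
                    flush(run)
                    run, skipped = [], 0
            continue
        if run:
            same_chrom = chroms[i] == chroms[run[-1]]
            same_dir = (deltas[i] > 0) == (deltas[run[-1]] > 0)
            within_gap = same_chrom and positions[i] - positions[run[-1]] <= th.max_gap
            within_span = th.max_span is None or positions[i] + 1 - positions[run[0]] <= th.max_span
            if same_chrom and same_dir and within_gap and within_span:
                run.append(i)
                skipped = 0
                continue
            flush(run)
            run, skipped = [], 0
        run = [i]
    flush(run)
    out = pd.DataFrame(dmrs, columns=DMR_COLUMNS)
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True) if len(out) else out


def pairwise_site_correlation(cohort: CohortTable, group_a: str, group_b: str) -> float:
    """Pearson r between two groups' pooled percents over the common sites."""
    _require_groups(cohort, group_a, group_b)
    a = cohort.group_percent[group_a].to_numpy()
    b = cohort.group_percent[group_b].to_numpy()
    ok = ~(np.isnan(a) | np.isnan(b))
    return pearson_r(a[ok], b[ok])


def dmr_cpg_matrix(cohort: CohortTable, dmrs: pd.DataFrame) -> pd.DataFrame:
    """Group-percent matrix over the union of member CpGs of all DMRs.

    Rows are (chrom, pos) of distinct member CpGs, columns are groups;
    suitable input to uncentered_avg_linkage.
    """
    if len(dmrs) == 0:
        return pd.DataFrame(columns=cohort.group_percent.columns)
    pairs = sorted(
        {(row.chrom, int(pos)) for row in dmrs.itertuples(index=False) for pos in row.members}
    )
    idx = pd.MultiIndex.from_tuples(pairs, names=["chrom", "pos"])
    gp = cohort.group_percent.copy()
    gp.index = cohort.site_index()
    return gp.loc[idx]
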
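"""Weak/strong rescue classification of knockout DMRs.

A knockout (KO) DMR is *strong* when it overlaps (>= 1 bp by default) a
catalytically-inactive (CI) DMR of the same direction: its methylation is not
restored by the inactive allele, so it depends on the enzyme's intrinsic
catalytic activity. A KO DMR with no such overlap is *weak*: the inactive
allele restores it, evidence of an accessory (non-catalytic) function.
CI DMRs overlapping no KO DMR are reported separately and excluded from the
weak/strong partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RescueSummary:
    n_total: int
    n_weak: int
    n_strong: int
    restoration_pct: float  # NaN (flagged) when n_total == 0
    n_ci_only: int
    overlap_pairs: list[tuple[int, int]] = field(default_factory=list)  # (ko index, ci index)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_weak + self.n_strong == self.n_total


def _interval_overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def classify_rescue(
    dmrs_ko: pd.DataFrame,
    dmrs_ci: pd.DataFrame,
    min_overlap_bp: int = 1,
    reciprocal_frac: float | None = None,
) -> tuple[pd.DataFrame, RescueSummary]:
    """Label each KO DMR weak or strong by same-direction overlap with CI DMRs.

    Both tables must come from same-reference (vs WT) comparisons with the
    same direction convention. ``reciprocal_frac``, if set, additionally
    requires the overlap to cover that fraction of both intervals.
    Returns (labeled copy of dmrs_ko, RescueSummary).
    """
    labeled = dmrs_ko.copy()
    labeled["label"] = "weak"
    pairs: list[tuple[int, int]] = []
    ci_hit = np.zeros(len(dmrs_ci), dtype=bool)
    ci_by_chrom: dict[str, list[tuple[int, int, int, str]]] = {}
    for j, row in enumerate(dmrs_ci.itertuples(index=False)):
        ci_by_chrom.setdefault(row.chrom, []).append((int(row.start), int(row.end), j, row.direction))
    for i, row in enumerate(dmrs_ko.itertuples(index=False)):
        for start, end, j, direction in ci_by_chrom.get(row.chrom, ()):
            if direction != row.direction:
                continue
            ov = _interval_overlap(row.start, row.end, start, end)
            if ov < min_overlap_bp:
                continue
            if reciprocal_frac is not None:
                if ov < reciprocal_frac * (row.end - row.start) or ov < reciprocal_frac * (end - start):
                    continue
            labeled.iloc[i, labeled.columns.get_loc("label")] = "strong"
            pairs.append((i, j))
            ci_hit[j] = True
    n_total = len(dmrs_ko)
    n_strong = int((labeled["label"] == "strong").sum())
    n_weak = n_total - n_strong
    flags = []
    if n_total == 0:
        pct = float("nan")
        flags.append("empty-ko-set")
    else:
        pct = 100.0 * n_weak / n_total
    summary = RescueSummary(
        n_total=n_total, n_weak=n_weak, n_strong=n_strong, restoration_pct=pct,
        n_ci_only=int((~ci_hit).sum()), overlap_pairs=pairs, flags=flags,
    )
    return labeled, summary


def restoration_report(summary: RescueSummary) -> pd.DataFrame:
    """One-row table of rescue counts; percentage reported to one decimal."""
    pct = summary.restoration_pct
    return pd.DataFrame(
        [
            {
                "n_ko_dmrs": summary.n_total,
                "n_weak": summary.n_weak,
                "n_strong": summary.n_strong,
                "restoration_pct": round(pct, 1) if np.isfinite(pct) else float("nan"),
                "n_ci_only": summary.n_ci_only,
            }
        ]
    )


def retest_rescue_levels(
    labeled: pd.DataFrame,
    cohort,
    reference: str = "WT",
    ci_group: str = "CI",
    min_diff: float = 30.0,
) -> pd.DataFrame:
    """Optional methylation-level re-test of the rescue labels.

    For users who read "rescued to wild-type levels" as a level re-test
    rather than interval overlap: a KO DMR is re-labeled strong when the mean
    CI-minus-WT pooled delta over its interval is at or beyond -min_diff
    (i.e. still hypomethylated in CI), weak otherwise. Adds a
    ``label_level`` column; intervals without covered CpGs keep the
    interval-overlap label.
    """
    sites = cohort.sites
    out = labeled.copy().reset_index(drop=True)
    levels = []
    for row in out.itertuples(index=False):
        mask = (
            (sites["chrom"].values == row.chrom)
            & (sites["pos"].values >= row.start)
            & (sites["pos"].values < row.end)
        )
        if not mask.any():
            levels.append(row.label)
            continue
        means = cohort.group_percent.loc[mask].mean()
        delta = means[ci_group] - means[reference]
        levels.append("strong" if delta <= -min_diff else "weak")
    out["label_level"] = levels
    return out


def summary_from_counts(n_total: int, n_weak: int, n_ci_only: int = 0) -> RescueSummary:
    """Build a RescueSummary from printed counts (worked-example arithmetic)."""
    if not 0 <= n_weak <= n_total:
        raise ValueError("need 0 <= n_weak <= n_total")
    pct = 100.0 * n_weak / n_total if n_total else float("nan")
    return RescueSummary(n_total=n_total, n_weak=n_weak, n_strong=n_total - n_weak,
                         restoration_pct=pct, n_ci_only=n_ci_only,
                         flags=[] if n_total else ["empty-ko-set"])
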
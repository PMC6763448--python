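"""Stage-to-stage (de novo / lost) methylation analysis.

Temporal DMRs are called with the same DMC/DMR machinery, using the early
stage as reference and the late stage as test within one genotype: hyper
DMRs are methylation gains (de novo), hypo DMRs are losses. Gains are then
classified by Dnmt3b dependence (hypomethylated in the knockout at the late
stage) and, among dependent gains, by mechanism: *accessory* when the
catalytically inactive allele restores the gain, *catalytic* when it does
not.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CohortTable, SampleProfile, build_cohort
from .dmr import Thresholds, call_dmcs, segment_dmrs


def temporal_dmrs(
    early: list[SampleProfile],
    late: list[SampleProfile],
    th: Thresholds | None = None,
) -> tuple[pd.DataFrame, CohortTable]:
    """Gains and losses between two stages of the same genotype.

    Common sites are intersected across all four (2+2) samples. Returns the
    DMR table with a ``direction`` of gain/loss plus the stage cohort.
    """
    th = th or Thresholds()
    genos = {p.genotype for p in early} | {p.genotype for p in late}
    if len(genos) > 1:
        raise ValueError(f"temporal comparison requires one genotype, got {sorted(genos)}")
    cohort = build_cohort({"early": early, "late": late}, min_cov=th.min_cov)
    dmcs = call_dmcs(cohort, reference="early", test="late", th=th)
    dmrs = segment_dmrs(dmcs, cohort, reference="early", test="late", th=th)
    dmrs = dmrs.copy()
    if len(dmrs):
        dmrs["direction"] = dmrs["direction"].map({"hyper": "gain", "hypo": "loss"})
    return dmrs, cohort


def _interval_group_means(cohort: CohortTable, chrom: str, start: int, end: int) -> pd.Series:
    sites = cohort.sites
    mask = (
        (sites["chrom"].values == chrom)
        & (sites["pos"].values >= start)
        & (sites["pos"].values < end)
    )
    if not mask.any():
        return pd.Series(dtype=float)
    return cohort.group_percent.loc[mask].mean()


def classify_dependence(
    gains: pd.DataFrame,
    cohort_late: CohortTable,
    th: Thresholds | None = None,
    wt: str = "WT",
    ko: str = "KO",
    ci: str = "CI",
    restore_window: float = 10.0,
) -> pd.DataFrame:
    """Label WT methylation gains by Dnmt3b dependence and mechanism.

    Dependence is re-tested per region on the late-stage all-genotype cohort:
    a gain is dnmt3b_dependent when the mean KO-WT pooled delta over its
    interval is <= -min_diff. Among dependent gains the mechanism is
    *accessory* when |CI - WT| < restore_window (the inactive allele suffices)
    and *catalytic* otherwise. Intervals with no covered CpG in the late
    cohort are labeled no-data.
    """
    th = th or Thresholds()
    out = gains.copy().reset_index(drop=True)
    dependence, mechanism = [], []
    for row in out.itertuples(index=False):
        means = _interval_group_means(cohort_late, row.chrom, row.start, row.end)
        if means.empty or means[[wt, ko, ci]].isna().any():
            dependence.append("no-data")
            mechanism.append("n/a")
            continue
        if means[ko] - means[wt] <= -th.min_diff:
            dependence.append("dnmt3b_dependent")
            mechanism.append("accessory" if abs(means[ci] - means[wt]) < restore_window else "catalytic")
        else:
            dependence.append("dnmt3b_independent")
            mechanism.append("n/a")
    out["dependence"] = dependence
    out["mechanism"] = mechanism
    return out


def de_novo_expression_link(
    annotated_gains: pd.DataFrame,
    de_results: pd.DataFrame,
    element_kinds: tuple[str, ...] = ("core_promoter", "enhancer"),
) -> pd.DataFrame:
    """Genes carrying a de novo methylation gain in a core promoter or
    enhancer that are also down-regulated between the stages.

    ``annotated_gains`` comes from genomic_annotation.annotate_dmrs;
    ``de_results`` from expression_integration.differential_expression with
    the late stage as test. The output is a subset of the down-regulated
    gene set by construction.
    """
    gene_cols = [f"{kind}_gene" for kind in element_kinds if f"{kind}_gene" in annotated_gains.columns]
    methylated_genes: set[str] = set()
    for col in gene_cols:
        kind = col[: -len("_gene")]
        hits = annotated_gains.loc[annotated_gains[kind] & (annotated_gains[col] != ""), col]
        methylated_genes.update(hits)
    down = de_results[de_results["status"] == "down"]
    linked = down[down["gene"].isin(methylated_genes)].copy()
    linked["n_candidate_genes"] = len(methylated_genes)
    return linked.reset_index(drop=True)
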
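"""Expression handling, the differential-expression stand-in, and
methylation-expression integration.

The DE caller here is deliberately simple: log2 fold change on group mean
FPKM with a 0.5 pseudocount, and a Welch t-test on log2(FPKM + 0.5) across
replicates. It is a documented stand-in for count-based negative-binomial
inference (the integration logic downstream, not the DE engine, is the point
of this package); its method field says so.

Promoter groups (genes whose long promoter is methylated in WT and
hypomethylated in the knockout):
  Group 1 - high WT FPKM, expression unchanged;
  Group 2 - low WT FPKM, unchanged;
  Group 3 - low WT FPKM, up-regulated on methylation loss.
(high, up) genes fall outside the published scheme and stay unassigned.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from scipy import special

from .stats import hypergeom_overlap, TestResult

PSEUDOCOUNT = 0.5
DE_METHOD = "welch-t-on-log2-fpkm (DESeq stand-in)"


def load_expression(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a gene x sample FPKM TSV.

    The first column is the gene id; a sample column named like
    ``WT_E11.5_rep1`` carries genotype, stage and replicate, which are parsed
    into the metadata table (columns sample, genotype, stage, replicate).
    Returns (matrix, metadata).
    """
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    if (matrix.values < 0).any():
        raise ValueError("negative FPKM values")
    meta_rows = []
    for col in matrix.columns:
        parts = col.split("_")
        meta_rows.append(
            {"sample": col,
             "genotype": parts[0] if len(parts) > 0 else "NA",
             "stage": parts[1] if len(parts) > 1 else "NA",
             "replicate": parts[2] if len(parts) > 2 else "rep1"}
        )
    return matrix, pd.DataFrame(meta_rows)


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def _group_columns(meta: pd.DataFrame, genotype: str, stage: str | None) -> list[str]:
    mask = meta["genotype"] == genotype
    if stage is not None:
        mask &= meta["stage"] == stage
    cols = meta.loc[mask, "sample"].tolist()
    if not cols:
        raise KeyError(f"no samples for genotype={genotype!r}, stage={stage!r}")
    return cols


def _vector_welch(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Welch p-values for two replicate blocks."""
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1 = x.var(axis=1, ddof=1) / n1
    v2 = y.var(axis=1, ddof=1) / n2
    denom = v1 + v2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m2) / np.sqrt(denom)
        df = denom ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = np.ones(len(t))
    ok = denom > 0
    p[ok] = 2.0 * special.stdtr(df[ok], -np.abs(t[ok]))
    zero_var_diff = (~ok) & (m1 != m2)
    p[zero_var_diff] = 0.0
    return p


def differential_expression(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    reference: str,
    test: str,
    stage: str | None = None,
    fc_min: float = 2.0,
    alpha: float = 0.05,
    reference_stage: str | None = None,
    test_stage: str | None = None,
) -> pd.DataFrame:
    """Per-gene log2 fold change (test vs reference) and Welch p-value.

    status is up when 2**log2FC >= fc_min (inclusive) and p < alpha; down
    symmetrically; ns otherwise. Genes with zero FPKM in both groups are ns
    and flagged. Requires >= 2 replicates per group. ``stage`` restricts both
    groups; ``reference_stage``/``test_stage`` override it per group for
    stage-to-stage comparisons within one genotype.
    """
    ref_cols = _group_columns(meta, reference, reference_stage or stage)
    test_cols = _group_columns(meta, test, test_stage or stage)
    if len(ref_cols) < 2 or len(test_cols) < 2:
        raise ValueError("differential_expression requires >= 2 replicates per group")
    ref = matrix[ref_cols].to_numpy(dtype=float)
    tst = matrix[test_cols].to_numpy(dtype=float)
    log2fc = np.log2(tst.mean(axis=1) + PSEUDOCOUNT) - np.log2(ref.mean(axis=1) + PSEUDOCOUNT)
    p = _vector_welch(np.log2(tst + PSEUDOCOUNT), np.log2(ref + PSEUDOCOUNT))
    all_zero = (ref.sum(axis=1) == 0) & (tst.sum(axis=1) == 0)
    log2_gate = np.log2(fc_min)
    status = np.where(
        (log2fc >= log2_gate) & (p < alpha), "up",
        np.where((log2fc <= -log2_gate) & (p < alpha), "down", "ns"),
    )
    status = np.where(all_zero, "ns", status)
    out = pd.DataFrame(
        {"gene": matrix.index, "log2_fold_change": log2fc, "p_value": p,
         "status": status, "all_zero": all_zero}
    ).reset_index(drop=True)
    out.attrs["method"] = DE_METHOD
    return out


def methylation_expression_overlap(
    hypo_genes: set[str] | list[str],
    de_results: pd.DataFrame,
    universe_n: int,
) -> tuple[pd.DataFrame, TestResult]:
    """Venn counts and hypergeometric p for genes that carry a hypomethylated
    DMR in the chosen element AND are up-regulated."""
    hypo = set(hypo_genes)
    up = set(de_results.loc[de_results["status"] == "up", "gene"])
    overlap = hypo & up
    res = hypergeom_overlap(len(overlap), len(hypo), len(up), universe_n)
    counts = pd.DataFrame(
        [{"n_hypo_genes": len(hypo), "n_up_genes": len(up),
          "n_overlap": len(overlap), "universe_n": universe_n, "p_value": res.p_value}]
    ).astype({"n_hypo_genes": int, "n_up_genes": int, "n_overlap": int, "universe_n": int})
    counts.attrs["overlap_genes"] = sorted(overlap)
    return counts, res


def classify_promoter_groups(
    candidate_genes: list[str],
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    de_results: pd.DataFrame,
    fpkm_high_cutoff: float = 1.0,
    wt: str = "WT",
    stage: str | None = None,
    fc_up: float = 2.0,
) -> pd.DataFrame:
    """Assign promoter-hypomethylated genes to Groups 1/2/3.

    Candidates are genes whose long promoter is methylated in WT and
    hypomethylated in the knockout. wt_fpkm_level is high when mean WT FPKM
    >= fpkm_high_cutoff; expression_change is up when the DE status is up
    with fold change > fc_up (strict, per the >2-fold inclusion rule).
    Groups: (high, unchanged) -> 1, (low, unchanged) -> 2, (low, up) -> 3;
    (high, up) and genes missing from the matrix stay unassigned (flagged).
    """
    wt_cols = _group_columns(meta, wt, stage)
    de = de_results.set_index("gene")
    rows = []
    for gene in candidate_genes:
        if gene not in matrix.index:
            rows.append({"gene": gene, "group": "unassigned", "wt_fpkm_level": "n/a",
                         "expression_change": "n/a", "flag": "absent-from-matrix"})
            continue
        wt_mean = float(matrix.loc[gene, wt_cols].mean())
        level = "high" if wt_mean >= fpkm_high_cutoff else "low"
        up = False
        if gene in de.index:
            rec = de.loc[gene]
            up = rec["status"] == "up" and 2.0 ** rec["log2_fold_change"] > fc_up
        change = "up" if up else "unchanged"
        if level == "high" and change == "unchanged":
            group = "1"
        elif level == "low" and change == "unchanged":
            group = "2"
        elif level == "low" and change == "up":
            group = "3"
        else:
            group = "unassigned"  # (high, up): outside the published scheme
        rows.append({"gene": gene, "group": group, "wt_fpkm_level": level,
                     "expression_change": change, "flag": ""})
    return pd.DataFrame(rows)


def group_mean_expression_report(
    assignments: pd.DataFrame,
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    genotypes: tuple[str, ...] = ("WT", "KO", "CI"),
    stage: str | None = None,
    normalizer_group: str = "3",
    normalizer_genotype: str = "WT",
) -> pd.DataFrame:
    """Per-group x genotype mean FPKM, normalized to the Group-3 WT mean."""
    rows = []
    raw: dict[tuple[str, str], float] = {}
    for group, sub in assignments[assignments["group"].isin(["1", "2", "3"])].groupby("group"):
        genes = [g for g in sub["gene"] if g in matrix.index]
        if not genes:
            continue
        for geno in genotypes:
            cols = _group_columns(meta, geno, stage)
            raw[(group, geno)] = float(matrix.loc[genes, cols].to_numpy().mean())
    norm = raw.get((normalizer_group, normalizer_genotype))
    if norm is None or norm == 0:
        raise ValueError("normalizer group/genotype mean unavailable or zero")
    for (group, geno), value in raw.items():
        rows.append({"group": group, "genotype": geno, "mean_fpkm": value,
                     "normalized_mean_fpkm": value / norm})
    return pd.DataFrame(rows).sort_values(["group", "genotype"]).reset_index(drop=True)
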
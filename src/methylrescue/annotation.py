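"""Genomic-element annotation of DMRs and imprinted-control-region reports.

A DMR is assigned to an element kind when a single element of that kind
covers at least ``min_overlap_frac`` of the DMR's length (default 50%,
inclusive, bedtools ``-f 0.5`` semantics). Kinds are non-exclusive: one DMR
may be, e.g., both a CGI and a core-promoter hit.

Promoter and gene-body windows (strand-aware, 0-based half-open):
long promoter = TSS-1500 .. TSS+500, core promoter = TSS-300 .. TSS+150,
gene body = TSS+500 .. transcript end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ELEMENT_KINDS = [
    "long_promoter", "core_promoter", "gene_body", "exon", "intron", "CGI", "enhancer", "repeat",
]

LONG_PROM_UP, LONG_PROM_DOWN = 1500, 500
CORE_PROM_UP, CORE_PROM_DOWN = 300, 150
GENE_BODY_OFFSET = 500


@dataclass
class AnnotationParams:
    min_overlap_frac: float = 0.5
    exclusive: bool = False  # if True, assign only the first matching kind in ELEMENT_KINDS order


class ElementCatalog:
    """Interval catalog keyed by element kind.

    ``df`` columns: chrom, start, end, kind, gene_id (optional, '' if absent).
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if "gene_id" not in df.columns:
            df["gene_id"] = ""
        if (df["end"] <= df["start"]).any():
            raise ValueError("element intervals must satisfy end > start")
        unknown = set(df["kind"]) - set(ELEMENT_KINDS)
        if unknown:
            raise ValueError(f"unknown element kinds: {sorted(unknown)}")
        self.df = df.sort_values(["kind", "chrom", "start"], kind="mergesort").reset_index(drop=True)

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.df[self.df["kind"] == kind]

    def kinds(self) -> list[str]:
        return [k for k in ELEMENT_KINDS if (self.df["kind"] == k).any()]

    @classmethod
    def concat(cls, catalogs: list["ElementCatalog"]) -> "ElementCatalog":
        return cls(pd.concat([c.df for c in catalogs], ignore_index=True))


def read_element_bed(path, kind: str) -> ElementCatalog:
    df = pd.read_csv(path, sep="\t", comment="#", header=None).iloc[:, :4]
    df.columns = ["chrom", "start", "end", "gene_id"][: df.shape[1]]
    df["kind"] = kind
    return ElementCatalog(df)


def read_icr_bed(path) -> pd.DataFrame:
    """ICR panel BED: chrom, start, end, name, icr_class (germline|somatic)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "name", "icr_class"])
    bad = set(df["icr_class"]) - {"germline", "somatic"}
    if bad:
        raise ValueError(f"unknown ICR classes: {sorted(bad)}")
    return df


def derive_elements(tss_table: pd.DataFrame) -> ElementCatalog:
    """Strand-aware promoter/gene-body windows from a TSS table.

    ``tss_table`` columns: gene_id, chrom, strand (+/-), tss, tx_end
    (tx_end is the transcript end in transcription order; for minus-strand
    genes it is numerically below the TSS). Transcripts shorter than the
    500 bp gene-body offset yield no gene-body interval (flagged via
    attrs['short_transcripts']).
    """
    rows = []
    short = []
    for row in tss_table.itertuples(index=False):
        tss = int(row.tss)
        if row.strand == "+":
            long_p = (tss - LONG_PROM_UP, tss + LONG_PROM_DOWN)
            core_p = (tss - CORE_PROM_UP, tss + CORE_PROM_DOWN)
            body = (tss + GENE_BODY_OFFSET, int(row.tx_end))
        elif row.strand == "-":
            # mirror the offsets around the TSS base (position tss, half-open)
            long_p = (tss + 1 - LONG_PROM_DOWN, tss + 1 + LONG_PROM_UP)
            core_p = (tss + 1 - CORE_PROM_DOWN, tss + 1 + CORE_PROM_UP)
            body = (int(row.tx_end), tss + 1 - GENE_BODY_OFFSET)
        else:
            raise ValueError(f"{row.gene_id}: strand must be '+' or '-'")
        for kind, (s, e) in (("long_promoter", long_p), ("core_promoter", core_p), ("gene_body", body)):
            s = max(0, s)
            if e > s:
                rows.append({"chrom": row.chrom, "start": s, "end": e, "kind": kind, "gene_id": row.gene_id})
            elif kind == "gene_body":
                short.append(row.gene_id)
    catalog = ElementCatalog(pd.DataFrame(rows, columns=["chrom", "start", "end", "kind", "gene_id"]))
    catalog.df.attrs["short_transcripts"] = short
    return catalog


def _max_single_overlap(start: int, end: int, elements: pd.DataFrame) -> tuple[int, str]:
    """Largest single-element overlap (bp) and that element's gene_id."""
    best, gene = 0, ""
    for row in elements.itertuples(index=False):
        ov = min(end, row.end) - max(start, row.start)
        if ov > best:
            best, gene = ov, row.gene_id
    return best, gene


def annotate_dmrs(dmrs: pd.DataFrame, catalog: ElementCatalog, params: AnnotationParams | None = None) -> pd.DataFrame:
    """Per-DMR element-kind assignment under the fractional-overlap rule.

    Returns a copy of ``dmrs`` with one boolean column per element kind in the
    catalog, plus ``<kind>_gene`` columns carrying the gene_id of the best
    overlapping element (where the kind is gene-linked).
    """
    params = params or AnnotationParams()
    out = dmrs.copy().reset_index(drop=True)
    kinds = catalog.kinds()
    by_kind_chrom: dict[tuple[str, str], pd.DataFrame] = {}
    for kind in kinds:
        sub = catalog.of_kind(kind)
        for chrom, grp in sub.groupby("chrom"):
            by_kind_chrom[(kind, chrom)] = grp
    assignments = {kind: np.zeros(len(out), dtype=bool) for kind in kinds}
    genes = {kind: np.full(len(out), "", dtype=object) for kind in kinds}
    for i, row in enumerate(out.itertuples(index=False)):
        length = row.end - row.start
        for kind in kinds:
            grp = by_kind_chrom.get((kind, row.chrom))
            if grp is None:
                continue
            ov, gene = _max_single_overlap(row.start, row.end, grp)
            if ov >= params.min_overlap_frac * length:
                assignments[kind][i] = True
                genes[kind][i] = gene
                if params.exclusive:
                    break
    for kind in kinds:
        out[kind] = assignments[kind]
        out[f"{kind}_gene"] = genes[kind]
    return out


def element_distribution(annotations: pd.DataFrame) -> pd.Series:
    """DMR count per element kind (non-exclusive indicator sums)."""
    kinds = [k for k in ELEMENT_KINDS if k in annotations.columns]
    return pd.Series({k: int(annotations[k].sum()) for k in kinds}, name="n_dmrs")


def chromosome_distribution(dmrs: pd.DataFrame) -> pd.Series:
    return dmrs.groupby("chrom").size().rename("n_dmrs")


def icr_report(
    cohort,
    panel: pd.DataFrame,
    wt: str = "WT",
    ko: str = "KO",
    ci: str = "CI",
    hypo_drop: float = 30.0,
    restore_window: float = 10.0,
) -> pd.DataFrame:
    """Per-ICR mean pooled percent per genotype plus hypomethylation/restoration calls.

    A locus is hypomethylated in the knockout when its WT mean minus KO mean
    is at least ``hypo_drop`` points, and restored in the CI genotype when
    |CI mean - WT mean| <= ``restore_window`` points. Loci without a common
    CpG are reported with no_data=True. The thresholds are declared
    assumptions (the published per-locus calls are qualitative).
    """
    sites = cohort.sites
    rows = []
    for row in panel.itertuples(index=False):
        in_locus = (
            (sites["chrom"].values == row.chrom)
            & (sites["pos"].values >= row.start)
            & (sites["pos"].values < row.end)
        )
        rec = {"name": row.name, "icr_class": row.icr_class, "n_cpgs": int(in_locus.sum())}
        if not in_locus.any():
            rec.update({f"{g}_mean": float("nan") for g in (wt, ko, ci)})
            rec.update({"hypo_in_ko": False, "restored_in_ci": False, "no_data": True})
        else:
            means = cohort.group_percent.loc[in_locus].mean()
            rec.update({f"{g}_mean": float(means[g]) for g in (wt, ko, ci)})
            hypo = means[wt] - means[ko] >= hypo_drop
            rec["hypo_in_ko"] = bool(hypo)
            rec["restored_in_ci"] = bool(hypo and abs(means[ci] - means[wt]) <= restore_window)
            rec["no_data"] = False
        rows.append(rec)
    return pd.DataFrame(rows)
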
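"""Synthetic cohort generator with machine-readable planted truth.

Emulates a three-genotype (WT, KO, CI) embryonic RRBS + RNA-seq study:

* per-CpG counts: negative-binomial coverage (default mean 30x) and
  beta-binomial methylation (precision chosen so the per-site percent SD at
  30x is ~9 points at 50% methylation, i.e. barely above binomial);
* planted differential regions, each a fixed run of CpGs at 25 bp spacing:
  ``weak`` (hypomethylated in KO only), ``strong`` (KO and CI), ``ci_only``
  (CI only), temporal ``gain``/``loss`` regions between two WT stages with
  per-region Dnmt3b dependence and accessory/catalytic mechanism;
* a 22 germline + 9 somatic imprinted-control-region panel whose per-locus
  genotype states follow the published per-locus descriptions;
* gene expression (3 replicates/genotype, log-normal noise) with planted
  fold changes and promoter-group structure (Groups 1/2/3); Group-3 genes
  are up-regulated through their promoter methylation loss, so the planted
  up-regulated total is the Group-3 count plus ``n_up_genes`` independent
  genes (253 with the defaults);
* smooth per-mark signal tracks with Gaussian enrichment bumps over
  designated region classes (repressive H3K27me3 over strong DMRs,
  activating H3K36me3/H3K4me2/H3K4me3 over weak DMRs).

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import ElementCatalog
from .io import SampleProfile
from .profiles import SignalTrack

GICR_NAMES = [
    "Impact", "Gnas1a", "Dlk1-Gtl2", "6330408a02Rik", "AK008011", "Snrpn", "Peg3",
    "Peg10", "Peg13", "Mest", "Plagl1", "Grb10", "Rasgrf1", "Kcnq1ot1", "Airn",
    "Zrsr1", "Nnat", "Nespas", "Mcts2", "Inpp5f", "Slc38a4", "Gpr1-Zdbf2",
]
GICR_HYPO = {"Gnas1a", "Dlk1-Gtl2", "6330408a02Rik", "AK008011"}
GICR_RESTORED = {"Gnas1a", "Dlk1-Gtl2"}

SICR_NAMES = ["Mkrn3", "Nesp", "Cdkn1c", "Gtl2", "H19", "Peg12", "Igf2r", "Gtl2-Mirg", "Eif2c2"]
SICR_HYPO = {"Mkrn3", "Nesp", "Cdkn1c", "Gtl2", "H19", "Peg12", "Igf2r"}
SICR_RESTORED = {"H19", "Nesp", "Gtl2", "Igf2r"}

DEFAULT_TRACK_ENRICHMENT = {
    # mark -> (enriched region class, fold enrichment)
    "H3K27me3": ("strong", 3.0),
    "H3K36me3": ("weak", 3.0),
    "H3K4me2": ("weak", 2.0),
    "H3K4me3": ("weak", 2.0),
}


@dataclass
class SimConfig:
    """Study-design parameters; defaults are the published study conditions."""

    seed: int = 1
    # genome
    n_chromosomes: int = 4
    chrom_length: int = 3_000_000
    n_genes: int = 400
    n_background_cpgs: int = 4000
    n_enhancers: int = 60
    n_repeats: int = 120
    # sequencing model
    coverage_mean: float = 30.0
    coverage_size: float = 50.0  # negative-binomial shape; var = m + m^2/size
    bb_precision: float = 1000.0  # beta-binomial alpha+beta
    replicates_rrbs: int = 2
    replicates_expr: int = 3
    # methylation landscape (percent)
    meth_high: float = 85.0
    meth_low: float = 5.0
    icr_base: float = 75.0
    # planted regions
    cpgs_per_region: int = 5
    cpg_spacing: int = 25
    n_weak: int = 4133
    n_strong: int = 205
    n_ci_only: int = 110
    n_gain: int = 133
    n_loss: int = 196
    n_gain_dependent: int = 18
    n_gain_catalytic: int = 4  # subset of the dependent gains
    n_denovo_promoters: int = 10  # gains placed in core promoters
    n_denovo_down: int = 3  # of those, genes down-regulated late vs early
    rescue_effect: float = 50.0
    temporal_effect: float = 40.0
    icr_effect: float = 40.0
    # stages
    early_stage: str = "E10.5"
    late_stage: str = "E11.5"
    # expression
    n_genes_expression: int = 12000
    n_up_genes: int = 219  # independent up genes; +34 Group-3 genes = 253 total
    n_down_genes: int = 819
    de_fc: float = 4.0
    expr_sigma: float = 0.2  # sd of ln(FPKM) noise
    group_counts: tuple[int, int, int] = (150, 163, 34)
    group_high_fpkm: float = 50.0
    group_low_fpkm: float = 0.2
    group3_fc: float = 8.0
    fpkm_base_mu: float = np.log(10.0)
    fpkm_base_sigma: float = 0.5
    # tracks
    track_bin_size: int = 10
    track_enrichment: dict = field(default_factory=lambda: dict(DEFAULT_TRACK_ENRICHMENT))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthSet:
    """Planted ground truth, BED-compatible coordinates throughout."""

    regions: pd.DataFrame  # chrom,start,end,klass,dependence,mechanism,gene_id
    icr_states: pd.DataFrame  # name,icr_class,chrom,start,end,hypo_in_ko,restored_in_ci
    de_genes: pd.DataFrame  # gene,comparison,direction
    promoter_groups: pd.DataFrame  # gene,group

    def regions_of(self, klass: str) -> pd.DataFrame:
        return self.regions[self.regions["klass"] == klass].reset_index(drop=True)

    def write(self, prefix) -> None:
        self.regions.to_csv(f"{prefix}_regions.tsv", sep="\t", index=False)
        self.icr_states.to_csv(f"{prefix}_icr.tsv", sep="\t", index=False)
        self.de_genes.to_csv(f"{prefix}_de_genes.tsv", sep="\t", index=False)
        self.promoter_groups.to_csv(f"{prefix}_groups.tsv", sep="\t", index=False)


@dataclass
class SyntheticGenome:
    catalog: ElementCatalog
    cpg_positions: pd.DataFrame  # chrom,pos (all simulated CpGs, sorted)
    tss_table: pd.DataFrame  # gene_id,chrom,strand,tss,tx_end
    icr_panel: pd.DataFrame  # chrom,start,end,name,icr_class
    truth: TruthSet
    config: SimConfig


def _region_cpgs(start: int, n: int, spacing: int) -> np.ndarray:
    return start + spacing * np.arange(n)


def simulate_genome(config: SimConfig | None = None) -> SyntheticGenome:
    """Lay out genes, elements, the ICR panel, planted regions and CpGs.

    Genes occupy the head of each chromosome; the ICR block and the
    intergenic planted-region block follow; background CpGs avoid planted
    footprints so region truth stays clean. Fully deterministic in the seed.
    """
    cfg = config or SimConfig()
    rng = cfg.rng()
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]

    # ---- genes -------------------------------------------------------------
    gene_rows = []
    gene_stride = 12_000
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chromosomes))
    g = 0
    for ci, chrom in enumerate(chroms):
        cursor = 10_000
        for _ in range(per_chrom):
            if g >= cfg.n_genes:
                break
            length = int(rng.integers(4_000, 9_000))
            strand = "+" if g % 2 == 0 else "-"
            if strand == "+":
                tss, tx_end = cursor, cursor + length
            else:
                tss, tx_end = cursor + length - 1, cursor
            gene_rows.append({"gene_id": f"gene{g + 1:04d}", "chrom": chrom, "strand": strand,
                              "tss": tss, "tx_end": tx_end, "g_start": cursor, "g_end": cursor + length})
            cursor += gene_stride
            g += 1
    genes = pd.DataFrame(gene_rows)
    genes_end = {chrom: int(genes.loc[genes["chrom"] == chrom, "g_end"].max() + 5_000)
                 if (genes["chrom"] == chrom).any() else 10_000 for chrom in chroms}

    from .annotation import derive_elements  # local import to avoid cycle at module load

    catalog = derive_elements(genes[["gene_id", "chrom", "strand", "tss", "tx_end"]])
    element_frames = [catalog.df]

    # exons/introns: three exons per gene within the gene body
    exin = []
    for row in genes.itertuples(index=False):
        s, e = row.g_start, row.g_end
        length = e - s
        bounds = s + (length * np.array([0.0, 0.15, 0.35, 0.55, 0.8, 1.0])).astype(int)
        for i in range(0, 5, 2):
            exin.append({"chrom": row.chrom, "start": int(bounds[i]), "end": int(bounds[i + 1]),
                         "kind": "exon", "gene_id": row.gene_id})
        for i in range(1, 4, 2):
            exin.append({"chrom": row.chrom, "start": int(bounds[i]), "end": int(bounds[i + 1]),
                         "kind": "intron", "gene_id": row.gene_id})
    element_frames.append(pd.DataFrame(exin))

    # ---- gene roles --------------------------------------------------------
    n_group = sum(cfg.group_counts)
    n_roles = n_group + cfg.n_denovo_promoters
    if n_roles > cfg.n_genes:
        raise ValueError("n_genes too small for the requested group/de-novo gene counts")
    gene_ids = genes["gene_id"].tolist()
    group_genes = gene_ids[:n_group]
    denovo_genes = gene_ids[n_group:n_group + cfg.n_denovo_promoters]
    cgi_genes = gene_ids[n_group + cfg.n_denovo_promoters:]

    # CGIs over the promoters of the unplanted genes (low-methylation islands)
    cgi_rows = []
    gene_lookup = genes.set_index("gene_id")
    for gid in cgi_genes:
        row = gene_lookup.loc[gid]
        tss = int(row["tss"])
        cgi_rows.append({"chrom": row["chrom"], "start": max(0, tss - 500), "end": tss + 500,
                         "kind": "CGI", "gene_id": gid})
    # de novo target promoters are unmethylated pre-gain but are not CGIs in
    # the catalog sense; their low base level is set directly below.
    element_frames.append(pd.DataFrame(cgi_rows))

    # ---- ICR panel (chr1 tail) ----------------------------------------------
    icr_len, icr_gap, icr_cpg_spacing = 600, 400, 50
    icr_rows = []
    icr_cursor = genes_end[chroms[0]]
    for name in GICR_NAMES:
        icr_rows.append({"chrom": chroms[0], "start": icr_cursor, "end": icr_cursor + icr_len,
                         "name": name, "icr_class": "germline"})
        icr_cursor += icr_len + icr_gap
    for name in SICR_NAMES:
        icr_rows.append({"chrom": chroms[0], "start": icr_cursor, "end": icr_cursor + icr_len,
                         "name": name, "icr_class": "somatic"})
        icr_cursor += icr_len + icr_gap
    icr_panel = pd.DataFrame(icr_rows)
    genes_end[chroms[0]] = icr_cursor + 5_000

    # ---- planted regions ----------------------------------------------------
    if cfg.cpgs_per_region < 2:
        raise ValueError("planted regions need at least 2 CpGs")
    region_span = cfg.cpg_spacing * (cfg.cpgs_per_region - 1) + 1
    region_stride = region_span + 500
    region_rows = []

    def add_region(chrom: str, start: int, klass: str, gene_id: str = "",
                   dependence: str = "", mechanism: str = "") -> None:
        region_rows.append({"chrom": chrom, "start": int(start), "end": int(start) + region_span,
                            "klass": klass, "dependence": dependence, "mechanism": mechanism,
                            "gene_id": gene_id})

    # promoter-linked weak regions (one per group gene, inside the long promoter)
    for gid in group_genes:
        row = gene_lookup.loc[gid]
        tss = int(row["tss"])
        start = tss - 600 if row["strand"] == "+" else tss + 600 - region_span
        add_region(row["chrom"], start, "weak", gene_id=gid)
    # de novo gains in core promoters
    gain_budget = cfg.n_gain
    dep_left, cat_left = cfg.n_gain_dependent, cfg.n_gain_catalytic
    for gid in denovo_genes:
        row = gene_lookup.loc[gid]
        tss = int(row["tss"])
        start = tss - 150 if row["strand"] == "+" else tss + 150 - region_span
        dependence = "dnmt3b_independent"
        mechanism = "n/a"
        if dep_left > 0:
            dependence = "dnmt3b_dependent"
            mechanism = "catalytic" if cat_left > 0 else "accessory"
            dep_left -= 1
            cat_left -= 1 if mechanism == "catalytic" else 0
        add_region(row["chrom"], start, "gain", gene_id=gid, dependence=dependence, mechanism=mechanism)
        gain_budget -= 1

    # intergenic regions, round-robin over chromosomes
    intergenic_classes = (
        [("weak", "", "")] * (cfg.n_weak - len(group_genes))
        + [("strong", "", "")] * cfg.n_strong
        + [("ci_only", "", "")] * cfg.n_ci_only
    )
    for _ in range(max(0, gain_budget)):
        dependence = "dnmt3b_independent"
        mechanism = "n/a"
        if dep_left > 0:
            dependence = "dnmt3b_dependent"
            mechanism = "catalytic" if cat_left > 0 else "accessory"
            dep_left -= 1
            cat_left -= 1 if mechanism == "catalytic" else 0
        intergenic_classes.append(("gain", dependence, mechanism))
    intergenic_classes += [("loss", "", "")] * cfg.n_loss
    if cfg.n_weak < len(group_genes):
        raise ValueError("n_weak must cover the promoter-linked group genes")

    cursors = dict(genes_end)
    ci = 0
    for klass, dependence, mechanism in intergenic_classes:
        chrom = chroms[ci % len(chroms)]
        start = cursors[chrom]
        if start + region_stride > cfg.chrom_length - 1_000:
            raise ValueError(f"{chrom} too short for the requested planted regions")
        add_region(chrom, start, klass, dependence=dependence, mechanism=mechanism)
        cursors[chrom] = start + region_stride
        ci += 1
    regions = pd.DataFrame(
        region_rows,
        columns=["chrom", "start", "end", "klass", "dependence", "mechanism", "gene_id"],
    )

    # repeats: cover a subset of intergenic planted regions plus empty intervals
    rep_rows = []
    intergenic = regions[regions["gene_id"] == ""]
    n_over = min(cfg.n_repeats // 2, len(intergenic))
    if n_over:
        chosen = intergenic.iloc[:: max(1, len(intergenic) // n_over)].head(n_over)
        for row in chosen.itertuples(index=False):
            rep_rows.append({"chrom": row.chrom, "start": max(0, row.start - 100),
                             "end": row.end + 100, "kind": "repeat", "gene_id": ""})
    for i in range(cfg.n_repeats - len(rep_rows)):
        chrom = chroms[i % len(chroms)]
        start = int(rng.integers(cursors[chrom] + 2_000, cfg.chrom_length - 2_000))
        rep_rows.append({"chrom": chrom, "start": start, "end": start + int(rng.integers(200, 800)),
                         "kind": "repeat", "gene_id": ""})
    element_frames.append(pd.DataFrame(rep_rows))

    # enhancers: intergenic, assigned to a gene for the expression link
    enh_rows = []
    for i in range(cfg.n_enhancers):
        chrom = chroms[i % len(chroms)]
        start = int(rng.integers(cursors[chrom] + 2_000, cfg.chrom_length - 2_000))
        gid = gene_ids[int(rng.integers(0, len(gene_ids)))]
        enh_rows.append({"chrom": chrom, "start": start, "end": start + 1_000,
                         "kind": "enhancer", "gene_id": gid})
    element_frames.append(pd.DataFrame(enh_rows))

    catalog = ElementCatalog(pd.concat(element_frames, ignore_index=True))

    # ---- CpG positions -------------------------------------------------------
    cpg_frames = []
    for row in regions.itertuples(index=False):
        cpg_frames.append(pd.DataFrame({
            "chrom": row.chrom,
            "pos": _region_cpgs(row.start, cfg.cpgs_per_region, cfg.cpg_spacing),
        }))
    for row in icr_panel.itertuples(index=False):
        cpg_frames.append(pd.DataFrame({
            "chrom": row.chrom,
            "pos": _region_cpgs(row.start + 25, (row.end - row.start - 50) // icr_cpg_spacing + 1,
                                icr_cpg_spacing),
        }))
    planted = pd.concat(cpg_frames, ignore_index=True)

    # background CpGs avoid planted footprints (+-50 bp)
    keep_away = pd.concat(
        [regions[["chrom", "start", "end"]], icr_panel[["chrom", "start", "end"]]], ignore_index=True
    )
    bg_rows = {"chrom": [], "pos": []}
    per_chrom_bg = cfg.n_background_cpgs // cfg.n_chromosomes
    for chrom in chroms:
        blocks = keep_away[keep_away["chrom"] == chrom]
        starts = blocks["start"].to_numpy() - 50
        ends = blocks["end"].to_numpy() + 50
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        cand = rng.choice(cfg.chrom_length - 2_000, size=per_chrom_bg * 2, replace=False) + 1_000
        idx = np.searchsorted(starts, cand, side="right") - 1
        inside = (idx >= 0) & (cand < ends[np.clip(idx, 0, len(ends) - 1)]) if len(starts) else np.zeros(len(cand), bool)
        cand = np.sort(cand[~inside])[:per_chrom_bg]
        bg_rows["chrom"].extend([chrom] * len(cand))
        bg_rows["pos"].extend(cand.tolist())
    cpgs = (
        pd.concat([planted, pd.DataFrame(bg_rows)], ignore_index=True)
        .drop_duplicates(["chrom", "pos"])
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    cpgs["pos"] = cpgs["pos"].astype(np.int64)

    icr_truth = icr_panel.copy()
    icr_truth["hypo_in_ko"] = [
        name in (GICR_HYPO if klass == "germline" else SICR_HYPO)
        for name, klass in zip(icr_panel["name"], icr_panel["icr_class"])
    ]
    icr_truth["restored_in_ci"] = [
        name in (GICR_RESTORED if klass == "germline" else SICR_RESTORED)
        for name, klass in zip(icr_panel["name"], icr_panel["icr_class"])
    ]

    truth = TruthSet(
        regions=regions,
        icr_states=icr_truth[["name", "icr_class", "chrom", "start", "end", "hypo_in_ko", "restored_in_ci"]],
        de_genes=pd.DataFrame(columns=["gene", "comparison", "direction"]),
        promoter_groups=pd.DataFrame({
            "gene": group_genes,
            "group": (["1"] * cfg.group_counts[0] + ["2"] * cfg.group_counts[1] + ["3"] * cfg.group_counts[2]),
        }),
    )
    tss_table = genes[["gene_id", "chrom", "strand", "tss", "tx_end"]].copy()
    return SyntheticGenome(catalog=catalog, cpg_positions=cpgs, tss_table=tss_table,
                           icr_panel=icr_panel, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# methylation sampling
# ---------------------------------------------------------------------------

def _true_levels(genome: SyntheticGenome) -> dict[tuple[str, str], np.ndarray]:
    """Per-site true methylation fraction for each (genotype, stage) needed.

    Returns arrays aligned with genome.cpg_positions for WT early/late and
    KO/CI at the late stage.
    """
    cfg = genome.config
    sites = genome.cpg_positions
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()

    base = np.full(len(sites), cfg.meth_high)
    for row in genome.catalog.of_kind("CGI").itertuples(index=False):
        mask = (chrom_arr == row.chrom) & (pos_arr >= row.start) & (pos_arr < row.end)
        base[mask] = cfg.meth_low
    for row in genome.icr_panel.itertuples(index=False):
        mask = (chrom_arr == row.chrom) & (pos_arr >= row.start) & (pos_arr < row.end)
        base[mask] = cfg.icr_base

    wt_early = base.copy()
    wt_late = base.copy()
    ko_late = base.copy()
    ci_late = base.copy()

    def region_mask(row) -> np.ndarray:
        return (chrom_arr == row.chrom) & (pos_arr >= row.start) & (pos_arr < row.end)

    for row in genome.truth.regions.itertuples(index=False):
        m = region_mask(row)
        if row.klass in ("weak", "strong", "ci_only"):
            # rescue-class regions sit on high background; the effect is a
            # main-stage (late) hypomethylation in the affected genotypes
            if row.klass in ("weak", "strong"):
                ko_late[m] = base[m] - cfg.rescue_effect
            if row.klass in ("strong", "ci_only"):
                ci_late[m] = base[m] - cfg.rescue_effect
        elif row.klass == "gain":
            wt_early[m] = cfg.meth_low
            wt_late[m] = cfg.meth_low + cfg.temporal_effect
            if row.dependence == "dnmt3b_dependent":
                if row.mechanism == "catalytic":
                    ko_late[m] = cfg.meth_low
                    ci_late[m] = cfg.meth_low + cfg.temporal_effect / 4.0  # partial restoration
                else:  # accessory: the inactive allele suffices
                    ko_late[m] = cfg.meth_low
                    ci_late[m] = cfg.meth_low + cfg.temporal_effect
            else:
                ko_late[m] = cfg.meth_low + cfg.temporal_effect
                ci_late[m] = cfg.meth_low + cfg.temporal_effect
        elif row.klass == "loss":
            wt_early[m] = cfg.meth_high
            for arr in (wt_late, ko_late, ci_late):
                arr[m] = cfg.meth_high - cfg.temporal_effect

    for row in genome.truth.icr_states.itertuples(index=False):
        m = region_mask(row)
        if row.hypo_in_ko:
            ko_late[m] = cfg.icr_base - cfg.icr_effect
            if not row.restored_in_ci:
                ci_late[m] = cfg.icr_base - cfg.icr_effect

    return {
        ("WT", cfg.early_stage): wt_early,
        ("WT", cfg.late_stage): wt_late,
        ("KO", cfg.late_stage): ko_late,
        ("CI", cfg.late_stage): ci_late,
    }


def _sample_counts(levels: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Negative-binomial coverage, beta-binomial methylated counts."""
    n = len(levels)
    p_nb = cfg.coverage_size / (cfg.coverage_size + cfg.coverage_mean)
    cov = rng.negative_binomial(cfg.coverage_size, p_nb, size=n)
    frac = np.clip(levels / 100.0, 0.005, 0.995)
    a = frac * cfg.bb_precision
    b = (1.0 - frac) * cfg.bb_precision
    p_site = rng.beta(a, b)
    meth = rng.binomial(cov, p_site)
    return meth, cov - meth


def simulate_methylation(
    config: SimConfig | None = None,
    genome: SyntheticGenome | None = None,
) -> tuple[dict[str, SampleProfile], TruthSet, SyntheticGenome]:
    """Draw RRBS profiles for WT (both stages) and KO/CI (late stage).

    Returns (profiles keyed by sample id like ``WT_E11.5_rep1``, truth,
    genome). Planted regions must span at least 2 CpGs (guaranteed by the
    genome builder) or generation fails naming the region.
    """
    cfg = config or SimConfig()
    if genome is None:
        genome = simulate_genome(cfg)
    cfg = genome.config
    rng = np.random.default_rng(cfg.seed + 1)  # distinct stream from the genome layout
    sites = genome.cpg_positions
    levels = _true_levels(genome)
    too_small = genome.truth.regions["end"] - genome.truth.regions["start"] < cfg.cpg_spacing
    if too_small.any():
        bad = genome.truth.regions[too_small].iloc[0]
        raise ValueError(f"planted region {bad.chrom}:{bad.start}-{bad.end} spans too few CpGs")
    profiles: dict[str, SampleProfile] = {}
    for (genotype, stage), lvl in levels.items():
        for rep in range(1, cfg.replicates_rrbs + 1):
            meth, unmeth = _sample_counts(lvl, cfg, rng)
            sid = f"{genotype}_{stage}_rep{rep}"
            profiles[sid] = SampleProfile(
                sid, genotype, stage,
                pd.DataFrame({"chrom": sites["chrom"], "pos": sites["pos"],
                              "meth": meth.astype(np.int64), "unmeth": unmeth.astype(np.int64)}),
            )
    return profiles, genome.truth, genome


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimConfig | None = None,
    genome: SyntheticGenome | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Log-normal FPKM matrix with planted fold changes.

    Samples: WT at both stages, KO and CI at the late stage, each with
    ``replicates_expr`` replicates. Planted effects (KO vs WT at the late
    stage): ``n_up_genes`` up and ``n_down_genes`` down at ``de_fc``-fold
    among well-expressed filler genes, plus the Group-3 promoter genes up at
    ``group3_fc``-fold. The de novo promoter genes marked as responders are
    down-regulated at the late vs early stage in WT. Returns
    (matrix, metadata, de_truth).
    """
    cfg = config or SimConfig()
    if genome is None:
        genome = simulate_genome(cfg)
    cfg = genome.config
    rng = np.random.default_rng(cfg.seed + 2)
    genome_genes = genome.tss_table["gene_id"].tolist()
    n_filler = cfg.n_genes_expression - len(genome_genes)
    if n_filler < cfg.n_up_genes + cfg.n_down_genes:
        raise ValueError("n_genes_expression too small for the planted DE gene counts")
    genes = genome_genes + [f"xgene{i + 1:05d}" for i in range(n_filler)]

    base = np.exp(rng.normal(cfg.fpkm_base_mu, cfg.fpkm_base_sigma, size=len(genes)))
    groups = genome.truth.promoter_groups.set_index("gene")["group"] if len(genome.truth.promoter_groups) else pd.Series(dtype=object)
    gene_index = {g: i for i, g in enumerate(genes)}
    for gene, grp in groups.items():
        base[gene_index[gene]] = cfg.group_high_fpkm if grp == "1" else cfg.group_low_fpkm

    # planted DE genes among the filler genes (well-expressed by construction)
    filler_ids = genes[len(genome_genes):]
    up_genes = filler_ids[: cfg.n_up_genes]
    down_genes = filler_ids[cfg.n_up_genes: cfg.n_up_genes + cfg.n_down_genes]
    group3_genes = [g for g, grp in groups.items() if grp == "3"]

    ko_factor = np.ones(len(genes))
    for g in up_genes:
        ko_factor[gene_index[g]] = cfg.de_fc
    for g in down_genes:
        ko_factor[gene_index[g]] = 1.0 / cfg.de_fc
    for g in group3_genes:
        ko_factor[gene_index[g]] = cfg.group3_fc

    # stage effect in WT: de novo promoter responders go down late vs early
    denovo = genome.truth.regions
    denovo_genes = denovo.loc[(denovo["klass"] == "gain") & (denovo["gene_id"] != ""), "gene_id"].tolist()
    stage_down = denovo_genes[: cfg.n_denovo_down]
    late_factor = np.ones(len(genes))
    for g in stage_down:
        late_factor[gene_index[g]] = 1.0 / cfg.de_fc

    designs = [("WT", cfg.early_stage, np.ones(len(genes))),
               ("WT", cfg.late_stage, late_factor),
               ("KO", cfg.late_stage, late_factor * ko_factor),
               ("CI", cfg.late_stage, late_factor)]
    cols, meta_rows = {}, []
    for genotype, stage, factor in designs:
        for rep in range(1, cfg.replicates_expr + 1):
            sid = f"{genotype}_{stage}_rep{rep}"
            noise = np.exp(rng.normal(0.0, cfg.expr_sigma, size=len(genes)))
            cols[sid] = base * factor * noise
            meta_rows.append({"sample": sid, "genotype": genotype, "stage": stage, "replicate": f"rep{rep}"})
    matrix = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    meta = pd.DataFrame(meta_rows)
    de_truth = pd.concat([
        pd.DataFrame({"gene": up_genes, "comparison": "KO_vs_WT", "direction": "up"}),
        pd.DataFrame({"gene": group3_genes, "comparison": "KO_vs_WT", "direction": "up"}),
        pd.DataFrame({"gene": down_genes, "comparison": "KO_vs_WT", "direction": "down"}),
        pd.DataFrame({"gene": stage_down, "comparison": "late_vs_early", "direction": "down"}),
    ], ignore_index=True)
    genome.truth.de_genes = de_truth
    return matrix, meta, de_truth


# ---------------------------------------------------------------------------
# signal tracks
# ---------------------------------------------------------------------------

def simulate_tracks(
    config: SimConfig | None = None,
    genome: SyntheticGenome | None = None,
) -> dict[str, SignalTrack]:
    """Smooth background signal with Gaussian bumps over designated region classes.

    Each mark has baseline 1.0 modulated by a slow sinusoid plus mild noise;
    regions of the mark's enriched class receive a Gaussian bump raising the
    local mean to the configured fold enrichment.
    """
    cfg = config or SimConfig()
    if genome is None:
        genome = simulate_genome(cfg)
    cfg = genome.config
    rng = np.random.default_rng(cfg.seed + 3)
    nbins = cfg.chrom_length // cfg.track_bin_size
    chroms = sorted(genome.cpg_positions["chrom"].unique())
    tracks: dict[str, SignalTrack] = {}
    for mark, (klass, fold) in cfg.track_enrichment.items():
        values: dict[str, np.ndarray] = {}
        regions = genome.truth.regions_of(klass)
        for chrom in chroms:
            x = np.arange(nbins)
            background = 1.0 + 0.1 * np.sin(2 * np.pi * x / 5_000.0) + rng.normal(0.0, 0.05, nbins)
            arr = np.clip(background, 0.05, None)
            sub = regions[regions["chrom"] == chrom]
            for row in sub.itertuples(index=False):
                center = (row.start + row.end) / 2.0 / cfg.track_bin_size
                width = max(3.0, (row.end - row.start) / cfg.track_bin_size)
                lo = max(0, int(center - 4 * width))
                hi = min(nbins, int(center + 4 * width))
                if hi <= lo:
                    continue
                xs = np.arange(lo, hi)
                arr[lo:hi] += (fold - 1.0) * np.exp(-0.5 * ((xs - center) / width) ** 2)
            values[chrom] = arr
        tracks[mark] = SignalTrack(mark, cfg.track_bin_size, values)
    return tracks
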
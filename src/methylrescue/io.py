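"""Reading, writing and pooling of per-CpG bisulfite call files.

Two input dialects are supported: Bismark coverage files (1-based start)
and MethylDackel bedGraph files (0-based start). All internal coordinates
are 0-based half-open; counts are authoritative and percentages are always
recomputed from them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITE_COLUMNS = ["chrom", "pos", "meth", "unmeth"]


class ParseError(ValueError):
    """Raised for malformed call-file lines (carries the line number)."""


class ValidationError(ValueError):
    """Raised for semantically invalid inputs (negative counts etc.)."""


def _empty_sites() -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": pd.Series(dtype=object), "pos": pd.Series(dtype=np.int64),
         "meth": pd.Series(dtype=np.int64), "unmeth": pd.Series(dtype=np.int64)}
    )


@dataclass
class SampleProfile:
    """Ordered per-CpG methylated/unmethylated counts for one sample.

    ``sites`` holds columns chrom, pos (0-based), meth, unmeth, sorted by
    (chrom, pos) with no duplicate positions.
    """

    sample_id: str
    genotype: str
    stage: str
    sites: pd.DataFrame = field(default_factory=_empty_sites)

    def __post_init__(self) -> None:
        sites = self.sites
        if list(sites.columns) != SITE_COLUMNS:
            sites = sites[SITE_COLUMNS]
        if len(sites):
            if (sites["meth"] < 0).any() or (sites["unmeth"] < 0).any():
                raise ValidationError(f"{self.sample_id}: negative counts")
            sites = sites.sort_values(["chrom", "pos"], kind="mergesort")
            if sites.duplicated(["chrom", "pos"]).any():
                raise ValidationError(f"{self.sample_id}: duplicate (chrom, pos)")
        self.sites = sites.reset_index(drop=True)

    @property
    def coverage(self) -> pd.Series:
        return self.sites["meth"] + self.sites["unmeth"]

    @property
    def percent(self) -> pd.Series:
        """Percent methylation per site; NaN where coverage is zero."""
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.sites["meth"] / cov
        return pct.where(cov > 0)

    def __len__(self) -> int:
        return len(self.sites)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleProfile):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.genotype == other.genotype
            and self.stage == other.stage
            and self.sites.equals(other.sites)
        )


def _read_call_file(path, offset: int, sample_id, genotype, stage) -> SampleProfile:
    """Shared 6-column parser. ``offset`` converts start to 0-based."""
    chroms, poss, meths, unmeths = [], [], [], []
    sid = sample_id
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(f"{path}: line {lineno}: expected 6 tab-separated fields, got {len(parts)}")
            try:
                pos = int(parts[1]) + offset
                meth = int(parts[4])
                unmeth = int(parts[5])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if meth < 0 or unmeth < 0:
                raise ValidationError(f"{path}: line {lineno}: negative counts")
            chroms.append(parts[0])
            poss.append(pos)
            meths.append(meth)
            unmeths.append(unmeth)
    if sid is None:
        sid = str(path)
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": np.asarray(poss, dtype=np.int64),
         "meth": np.asarray(meths, dtype=np.int64), "unmeth": np.asarray(unmeths, dtype=np.int64)}
    ) if chroms else _empty_sites()
    return SampleProfile(sid, genotype or "NA", stage or "NA", sites)


def read_bismark_cov(path, sample_id=None, genotype=None, stage=None) -> SampleProfile:
    """Read a Bismark coverage file (chrom, start 1-based, end, percent, meth, unmeth)."""
    return _read_call_file(path, offset=-1, sample_id=sample_id, genotype=genotype, stage=stage)


def read_methyldackel_bedgraph(path, sample_id=None, genotype=None, stage=None) -> SampleProfile:
    """Read a MethylDackel bedGraph (chrom, start 0-based, end, percent, meth, unmeth)."""
    return _read_call_file(path, offset=0, sample_id=sample_id, genotype=genotype, stage=stage)


def write_bismark_cov(profile: SampleProfile, path) -> None:
    with open(path, "w") as fh:
        for chrom, pos, meth, unmeth in profile.sites.itertuples(index=False):
            cov = meth + unmeth
            pct = 100.0 * meth / cov if cov else 0.0
            fh.write(f"{chrom}\t{pos + 1}\t{pos + 1}\t{pct:.6g}\t{meth}\t{unmeth}\n")


def write_methyldackel_bedgraph(profile: SampleProfile, path) -> None:
    with open(path, "w") as fh:
        for chrom, pos, meth, unmeth in profile.sites.itertuples(index=False):
            cov = meth + unmeth
            pct = 100.0 * meth / cov if cov else 0.0
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{pct:.6g}\t{meth}\t{unmeth}\n")


def destrand(profile: SampleProfile) -> SampleProfile:
    """Merge plus/minus CpG calls at adjacent positions p and p+1 by summing counts.

    Off by default in all pipelines; use when input was not destranded by the
    methylation extractor. The merged site keeps the lower (plus-strand)
    coordinate.
    """
    sites = profile.sites
    if len(sites) < 2:
        return SampleProfile(profile.sample_id, profile.genotype, profile.stage, sites.copy())
    same_chrom = sites["chrom"].values[1:] == sites["chrom"].values[:-1]
    adjacent = sites["pos"].values[1:] == sites["pos"].values[:-1] + 1
    partner = same_chrom & adjacent
    # greedy left-to-right pairing: a site already merged cannot start a pair
    group = np.arange(len(sites))
    taken = False
    for i in range(len(sites) - 1):
        if partner[i] and not taken:
            group[i + 1] = group[i]
            taken = True
        else:
            taken = False
    merged = (
        sites.assign(_g=group)
        .groupby("_g", sort=False)
        .agg(chrom=("chrom", "first"), pos=("pos", "first"), meth=("meth", "sum"), unmeth=("unmeth", "sum"))
        .reset_index(drop=True)
    )
    return SampleProfile(profile.sample_id, profile.genotype, profile.stage, merged)


def pool_group(profiles: list[SampleProfile], sample_id: str | None = None) -> SampleProfile:
    """Sum replicate counts per position into one group-level profile.

    All profiles must share genotype and stage. The pooled percent at a site
    equals the coverage-weighted mean of the replicate percents.
    """
    if not profiles:
        raise ValidationError("pool_group needs at least one profile")
    genotypes = {p.genotype for p in profiles}
    stages = {p.stage for p in profiles}
    if len(genotypes) > 1 or len(stages) > 1:
        raise ValidationError(f"mixed genotypes/stages in pool: {sorted(genotypes)}, {sorted(stages)}")
    sid = sample_id or f"pooled_{profiles[0].genotype}_{profiles[0].stage}"
    if len(profiles) == 1:
        return SampleProfile(sid, profiles[0].genotype, profiles[0].stage, profiles[0].sites.copy())
    pooled = (
        pd.concat([p.sites for p in profiles], ignore_index=True)
        .groupby(["chrom", "pos"], as_index=False, sort=True)[["meth", "unmeth"]]
        .sum()
    )
    return SampleProfile(sid, profiles[0].genotype, profiles[0].stage, pooled)


@dataclass
class CohortTable:
    """Group-pooled methylation at CpG sites covered in all samples.

    ``sites`` is the ordered common-site table (chrom, pos). ``group_percent``
    and the pooled count frames are indexed like ``sites``; columns are group
    labels. ``per_sample_percent`` columns are (group, sample_id) pairs.
    """

    groups: dict[str, list[SampleProfile]]
    sites: pd.DataFrame
    group_percent: pd.DataFrame
    group_meth: pd.DataFrame
    group_cov: pd.DataFrame
    per_sample_percent: pd.DataFrame
    min_cov: int

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def group_labels(self) -> list[str]:
        return list(self.groups)

    def site_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.sites[["chrom", "pos"]])


def build_cohort(groups: dict[str, list[SampleProfile]], min_cov: int = 15) -> CohortTable:
    """Restrict to sites covered >= min_cov in every sample, pool per group.

    The coverage filter is applied per sample before intersecting, so the
    common set is the intersection of each sample's adequately covered sites.
    An empty intersection yields an empty table with a warning, not an error.
    """
    if min_cov < 1:
        raise ValidationError("min_cov must be >= 1")
    if not groups or any(not members for members in groups.values()):
        raise ValidationError("every group needs at least one sample")
    common: pd.MultiIndex | None = None
    for members in groups.values():
        for prof in members:
            cov = prof.coverage
            kept = prof.sites.loc[cov >= min_cov, ["chrom", "pos"]]
            idx = pd.MultiIndex.from_frame(kept)
            common = idx if common is None else common.intersection(idx)
    assert common is not None
    common = common.sortlevel([0, 1])[0]
    if len(common) == 0:
        warnings.warn("no CpG site passes the coverage filter in all samples", stacklevel=2)
    sites = pd.DataFrame({"chrom": common.get_level_values(0), "pos": common.get_level_values(1)})

    group_meth, group_cov, per_sample = {}, {}, {}
    for label, members in groups.items():
        meth_sum = np.zeros(len(common))
        cov_sum = np.zeros(len(common))
        for prof in members:
            indexed = prof.sites.set_index(["chrom", "pos"])
            sub = indexed.reindex(common)
            m = sub["meth"].to_numpy(dtype=float)
            u = sub["unmeth"].to_numpy(dtype=float)
            meth_sum += m
            cov_sum += m + u
            with np.errstate(invalid="ignore"):
                per_sample[(label, prof.sample_id)] = 100.0 * m / (m + u)
        group_meth[label] = meth_sum
        group_cov[label] = cov_sum
    gm = pd.DataFrame(group_meth)
    gc = pd.DataFrame(group_cov)
    with np.errstate(invalid="ignore", divide="ignore"):
        gp = 100.0 * gm / gc
    psp = pd.DataFrame(per_sample)
    psp.columns = pd.MultiIndex.from_tuples(psp.columns, names=["group", "sample"])
    return CohortTable(groups=groups, sites=sites, group_percent=gp, group_meth=gm,
                       group_cov=gc, per_sample_percent=psp, min_cov=min_cov)


DMR_BED_HEADER = "#chrom\tstart\tend\tname\tscore\tstrand\tn_dmcs\tmean_delta\tp_value\tdirection\tlabel"


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """Write DMRs as BED6+ (0-based half-open); score = round(|mean_delta|)."""
    with open(path, "w") as fh:
        fh.write(DMR_BED_HEADER + "\n")
        if dmrs is None or len(dmrs) == 0:
            return
        for i, row in enumerate(dmrs.itertuples(index=False)):
            label = getattr(row, "label", ".")
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\tDMR_{i + 1}\t"
                f"{round(abs(row.mean_delta))}\t.\t{row.n_dmcs}\t{row.mean_delta:.6g}\t"
                f"{row.p_value:.6g}\t{row.direction}\t{label}\n"
            )


def read_dmr_bed(path) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "n_dmcs", "mean_delta", "p_value", "direction", "label"]
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=cols)
    return df.astype({"start": np.int64, "end": np.int64}) if len(df) else df
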
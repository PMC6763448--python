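"""Meta-profiles of methylation and chromatin signal.

Signal is consumed as pre-binned bedGraph (fixed, non-overlapping bins).
Two profile modes: TSS-relative windows (strand-aware, upstream negative)
and length-scaled region bodies with unscaled flanks, as produced by
deepTools-style scaled-region matrices. Enrichment comparisons summarize
each region by its mean signal over the (unscaled) body and apply a Welch
t-test between region sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import welch_t, student_t, TestResult


@dataclass
class SignalTrack:
    """Fixed-bin signal values per chromosome; bin i covers
    [i*bin_size, (i+1)*bin_size)."""

    mark: str
    bin_size: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def mean_over(self, chrom: str, start: float, end: float) -> float:
        """Coverage-weighted mean signal over [start, end); NaN if no data."""
        arr = self.values.get(chrom)
        if arr is None or end <= start:
            return float("nan")
        lo = start / self.bin_size
        hi = end / self.bin_size
        first, last = int(np.floor(lo)), int(np.ceil(hi))
        total, weight = 0.0, 0.0
        for b in range(max(0, first), min(len(arr), last)):
            ov = min(end, (b + 1) * self.bin_size) - max(start, b * self.bin_size)
            if ov > 0:
                total += arr[b] * ov
                weight += ov
        return total / weight if weight else float("nan")


def load_signal_track(path, mark: str | None = None) -> SignalTrack:
    """Read a fixed-bin bedGraph; overlapping or ragged intervals are errors."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["chrom", "start", "end", "value"],
                         skiprows=_n_track_lines(path))
    except pd.errors.EmptyDataError:
        return SignalTrack(mark or str(path), 1, {})
    if len(df) == 0:
        return SignalTrack(mark or str(path), 1, {})
    widths = (df["end"] - df["start"]).unique()
    if len(widths) != 1 or widths[0] <= 0:
        raise ValueError(f"{path}: expected fixed-width bins, got widths {sorted(widths)[:5]}")
    bin_size = int(widths[0])
    if (df["start"] % bin_size).any():
        raise ValueError(f"{path}: bins not aligned to the bin size")
    values: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom"):
        idx = (grp["start"] // bin_size).to_numpy()
        if len(np.unique(idx)) != len(idx):
            raise ValueError(f"{path}: overlapping intervals on {chrom}")
        arr = np.zeros(int(idx.max()) + 1)
        arr[idx] = grp["value"].to_numpy()
        values[chrom] = arr
    track = SignalTrack(mark or str(path), bin_size, values)
    if not all(np.isfinite(a).all() for a in values.values()):
        raise ValueError(f"{path}: non-finite signal values")
    return track


def _n_track_lines(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("track"):
                n += 1
            else:
                break
    return n


def write_signal_track(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            for i, v in enumerate(arr):
                fh.write(f"{chrom}\t{i * track.bin_size}\t{(i + 1) * track.bin_size}\t{v:.8g}\n")


@dataclass
class MetaProfile:
    """Per-bin mean +- SEM across regions/TSSs.

    ``bin_coords`` is TSS-relative bp in TSS mode, or bin index with flank
    bins negative/past-body in scaled mode. ``n`` is the number of regions
    contributing to each bin.
    """

    bin_coords: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    mode: str


def _accumulate(per_region_rows: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    stacked = np.vstack(per_region_rows)
    n = np.sum(~np.isnan(stacked), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins are legitimate
        mean = np.nanmean(stacked, axis=0)
        sd = np.nanstd(stacked, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    return mean, sem, n


def _methylation_values(source) -> pd.DataFrame:
    """Normalize a methylation source to a (chrom, pos, value) frame.

    Accepts a DataFrame with those columns, or a (CohortTable, group) pair.
    """
    if isinstance(source, pd.DataFrame):
        return source
    cohort, group = source
    return pd.DataFrame(
        {"chrom": cohort.sites["chrom"], "pos": cohort.sites["pos"],
         "value": cohort.group_percent[group].to_numpy()}
    )


def _region_binned(source, chrom: str, edges: np.ndarray) -> np.ndarray:
    """Mean value per [edges[i], edges[i+1]) bin for either source type."""
    nbins = len(edges) - 1
    out = np.full(nbins, np.nan)
    if isinstance(source, SignalTrack):
        # edges may be fractional (scaled bodies); mean_over handles floats
        for b in range(nbins):
            out[b] = source.mean_over(chrom, edges[b], edges[b + 1])
        return out
    sub = source[source["chrom"] == chrom]
    pos = sub["pos"].to_numpy()
    val = sub["value"].to_numpy()
    which = np.searchsorted(edges, pos, side="right") - 1
    ok = (which >= 0) & (which < nbins) & (pos >= edges[0]) & (pos < edges[-1])
    sums = np.zeros(nbins)
    counts = np.zeros(nbins)
    np.add.at(sums, which[ok], val[ok])
    np.add.at(counts, which[ok], 1)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out


def tss_meta_profile(source, tss_table: pd.DataFrame, half_window: int, bin_size: int) -> MetaProfile:
    """Mean +- SEM per TSS-relative bin; strand-aware (upstream negative).

    ``source`` is a SignalTrack, a (chrom, pos, value) methylation frame, or
    a (CohortTable, group) pair. TSSs contributing no data to a bin are
    excluded from that bin's n.
    """
    if half_window % bin_size:
        raise ValueError("half_window must be a multiple of bin_size")
    if not isinstance(source, SignalTrack):
        source = _methylation_values(source)
    nbins = 2 * half_window // bin_size
    rows = []
    for row in tss_table.itertuples(index=False):
        tss = int(row.tss)
        edges = tss - half_window + np.arange(nbins + 1) * bin_size
        vals = _region_binned(source, row.chrom, edges.astype(float))
        if getattr(row, "strand", "+") == "-":
            vals = vals[::-1]
        rows.append(vals)
    if not rows:
        raise ValueError("tss_table is empty")
    mean, sem, n = _accumulate(rows)
    centers = -half_window + bin_size * (np.arange(nbins) + 0.5)
    return MetaProfile(bin_coords=centers, mean=mean, sem=sem, n=n, mode="tss")


def scaled_region_profile(
    source,
    regions: pd.DataFrame,
    body_bins: int = 100,
    bin_size: int = 10,
    flank: int = 100,
) -> MetaProfile:
    """Length-scaled body (``body_bins`` bins) with unscaled flanks.

    Each region body is rescaled onto ``body_bins`` equal sub-intervals; the
    flanks are covered by fixed ``bin_size`` bins. For a region whose length
    equals body_bins * bin_size the scaling is the identity.
    """
    if len(regions) == 0:
        raise ValueError("regions is empty")
    if flank % bin_size:
        raise ValueError("flank must be a multiple of bin_size")
    if not isinstance(source, SignalTrack):
        source = _methylation_values(source)
    flank_bins = flank // bin_size
    rows = []
    for row in regions.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        left = start - flank + np.arange(flank_bins + 1) * bin_size
        body = start + (end - start) * np.arange(body_bins + 1) / body_bins
        right = end + np.arange(flank_bins + 1) * bin_size
        vals = np.concatenate(
            [
                _region_binned(source, row.chrom, left.astype(float)),
                _region_binned(source, row.chrom, body),
                _region_binned(source, row.chrom, right.astype(float)),
            ]
        )
        rows.append(vals)
    mean, sem, n = _accumulate(rows)
    coords = np.arange(-flank_bins, body_bins + flank_bins)
    return MetaProfile(bin_coords=coords, mean=mean, sem=sem, n=n, mode="scaled")


def region_means(track: SignalTrack, regions: pd.DataFrame) -> np.ndarray:
    """Per-region mean signal over the unscaled body (flanks excluded)."""
    return np.array([track.mean_over(r.chrom, int(r.start), int(r.end)) for r in regions.itertuples(index=False)])


def compare_enrichment(
    track: SignalTrack,
    regions_a: pd.DataFrame,
    regions_b: pd.DataFrame,
    test: str = "welch",
) -> TestResult:
    """Welch (default) or Student t-test of per-region mean signal, A vs B."""
    a = region_means(track, regions_a)
    b = region_means(track, regions_b)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    fn = welch_t if test == "welch" else student_t
    return fn(a, b)


def stratified_enrichment(
    track: SignalTrack,
    annotated_a: pd.DataFrame,
    annotated_b: pd.DataFrame,
    kinds: list[str],
    test: str = "welch",
) -> pd.DataFrame:
    """compare_enrichment within each element-kind stratum.

    Inputs are annotate_dmrs outputs for the two region sets; strata with
    fewer than two regions on either side are reported as no-test.
    """
    rows = []
    for kind in kinds:
        sub_a = annotated_a[annotated_a.get(kind, False) == True] if kind in annotated_a else annotated_a.iloc[0:0]  # noqa: E712
        sub_b = annotated_b[annotated_b.get(kind, False) == True] if kind in annotated_b else annotated_b.iloc[0:0]  # noqa: E712
        if len(sub_a) < 2 or len(sub_b) < 2:
            rows.append({"kind": kind, "n_a": len(sub_a), "n_b": len(sub_b),
                         "mean_a": float("nan"), "mean_b": float("nan"),
                         "statistic": float("nan"), "p_value": float("nan"), "tested": False})
            continue
        res = compare_enrichment(track, sub_a, sub_b, test=test)
        rows.append({"kind": kind, "n_a": len(sub_a), "n_b": len(sub_b),
                     "mean_a": float(np.nanmean(region_means(track, sub_a))),
                     "mean_b": float(np.nanmean(region_means(track, sub_b))),
                     "statistic": res.statistic, "p_value": res.p_value, "tested": True})
    return pd.DataFrame(rows)
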
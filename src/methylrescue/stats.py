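"""Statistical primitives used throughout the pipeline.

Implemented here rather than delegated: the Mann-Whitney U test switches to
an exact enumeration-based null when the pooled sample is small (regions of
3-10 CpGs x 2 replicates live exactly where the normal approximation is
poor), and the clustering uses the uncentered-correlation (cosine) distance
with average linkage. scipy supplies only distribution CDFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import special

EXACT_MWU_MAX_N = 16  # n1 + n2 at or below this (and no ties) -> exact null


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    tails: str
    n1: int
    n2: int
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")


@lru_cache(maxsize=None)
def _exact_u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Number of rank assignments giving each U value, for tie-free data.

    Standard recursion over placing the largest observation in either sample:
    c(n1, n2, u) = c(n1-1, n2, u-n2) + c(n1, n2-1, u).
    """
    if n1 == 0 or n2 == 0:
        return (1,)
    a = _exact_u_counts(n1 - 1, n2)
    b = _exact_u_counts(n1, n2 - 1)
    size = n1 * n2 + 1
    out = [0] * size
    for u, c in enumerate(a):
        out[u + n2] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def _u_statistic(xs: np.ndarray, ys: np.ndarray) -> float:
    """U for xs over ys, counting ties as one half."""
    diff = xs[:, None] - ys[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney_u(xs, ys) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution by enumeration when n1 + n2 <= 16 and the pooled
    data are tie-free; otherwise a normal approximation with tie and
    continuity corrections. Degenerate input (a single pooled value) returns
    p = 1 with a flag.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n1, n2 = len(xs), len(ys)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([xs, ys])
    flags: list[str] = []
    u1 = _u_statistic(xs, ys)
    if np.ptp(pooled) == 0:
        return TestResult(u1, 1.0, "mwu-degenerate", "two", n1, n2, ["degenerate"])
    has_ties = len(np.unique(pooled)) < n1 + n2
    if n1 + n2 <= EXACT_MWU_MAX_N and not has_ties:
        counts = _exact_u_counts(n1, n2)
        total = sum(counts)
        u_small = min(u1, n1 * n2 - u1)
        tail = sum(counts[: int(u_small) + 1])
        p = min(1.0, 2.0 * tail / total)
        return TestResult(u1, p, "mwu-exact", "two", n1, n2, flags)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return TestResult(u1, 1.0, "mwu-degenerate", "two", n1, n2, ["degenerate"])
    z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * special.ndtr(-z))
    return TestResult(u1, p, "mwu-normal", "two", n1, n2, flags)


def _t_two_sided_p(t: float, df: float) -> float:
    return float(2.0 * special.stdtr(df, -abs(t)))


def welch_t(xs, ys) -> TestResult:
    """Two-tailed Welch's t-test with Welch-Satterthwaite degrees of freedom."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n1, n2 = len(xs), len(ys)
    if n1 < 2 or n2 < 2:
        raise ValueError("welch_t needs at least two observations per group")
    v1 = xs.var(ddof=1) / n1
    v2 = ys.var(ddof=1) / n2
    if v1 + v2 == 0:
        p = 1.0 if xs.mean() == ys.mean() else 0.0
        return TestResult(0.0 if p == 1.0 else np.inf, p, "welch-degenerate", "two", n1, n2, ["zero-variance"])
    t = (xs.mean() - ys.mean()) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return TestResult(float(t), _t_two_sided_p(t, df), "welch", "two", n1, n2)


def student_t(xs, ys) -> TestResult:
    """Two-tailed Student's t-test (pooled variance); Welch is the default elsewhere."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n1, n2 = len(xs), len(ys)
    if n1 < 2 or n2 < 2:
        raise ValueError("student_t needs at least two observations per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * xs.var(ddof=1) + (n2 - 1) * ys.var(ddof=1)) / df
    if sp2 == 0:
        p = 1.0 if xs.mean() == ys.mean() else 0.0
        return TestResult(0.0 if p == 1.0 else np.inf, p, "student-degenerate", "two", n1, n2, ["zero-variance"])
    t = (xs.mean() - ys.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return TestResult(float(t), _t_two_sided_p(t, df), "student", "two", n1, n2)


def chi_square_gof(observed, expected_ratios) -> TestResult:
    """Chi-squared goodness of fit of observed counts against expected proportions."""
    obs = np.asarray(observed, dtype=float)
    ratios = np.asarray(expected_ratios, dtype=float)
    if obs.shape != ratios.shape:
        raise ValueError("observed and expected_ratios must have the same length")
    if not np.isclose(ratios.sum(), 1.0):
        raise ValueError("expected ratios must sum to 1")
    if (ratios <= 0).any():
        raise ValueError("expected ratios must be positive")
    exp = ratios * obs.sum()
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    p = float(special.chdtrc(df, stat))
    return TestResult(stat, p, "chi-square-gof", "two", len(obs), len(obs))


def _hypergeom_logpmf(k: int, N: int, nA: int, nB: int) -> float:
    return (
        special.gammaln(nA + 1) - special.gammaln(k + 1) - special.gammaln(nA - k + 1)
        + special.gammaln(N - nA + 1) - special.gammaln(nB - k + 1) - special.gammaln(N - nA - nB + k + 1)
        - (special.gammaln(N + 1) - special.gammaln(nB + 1) - special.gammaln(N - nB + 1))
    )


def hypergeom_overlap(k: int, nA: int, nB: int, N: int) -> TestResult:
    """One-sided over-representation p-value P(X >= k) for an overlap of k
    between sets of sizes nA and nB drawn from a universe of N."""
    if not (0 <= k <= min(nA, nB) <= N):
        raise ValueError("need 0 <= k <= min(nA, nB) <= N")
    kmax = min(nA, nB)
    kmin_support = max(0, nA + nB - N)
    lo = max(k, kmin_support)
    if lo > kmax:
        p = 0.0
    else:
        ks = np.arange(lo, kmax + 1)
        logs = np.array([_hypergeom_logpmf(int(kk), N, nA, nB) for kk in ks])
        p = float(min(1.0, np.exp(special.logsumexp(logs))))
    return TestResult(float(k), p, "hypergeometric", "one", nA, nB)


def pearson_r(xs, ys) -> float:
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) != len(ys) or len(xs) < 2:
        raise ValueError("pearson_r needs two equal-length vectors of >= 2 values")
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return float("nan")
    return float((xc * yc).sum() / denom)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; raw p is the default gate)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class ClusterTree:
    """Agglomerative clustering result.

    ``merges`` rows are (left_id, right_id, height, size); leaves are ids
    0..n-1, internal nodes n, n+1, ... in merge order, as in scipy linkage.
    """

    n_leaves: int
    merges: list[tuple[int, int, float, int]]
    labels: list[str]
    flags: list[str] = field(default_factory=list)

    @property
    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf order of the dendrogram."""
        children = {self.n_leaves + i: (m[0], m[1]) for i, m in enumerate(self.merges)}
        root = self.n_leaves + len(self.merges) - 1
        order: list[int] = []
        stack = [root]
        while stack:
            node = stack.pop()
            if node < self.n_leaves:
                order.append(node)
            else:
                left, right = children[node]
                stack.append(right)
                stack.append(left)
        return order

    def to_newick(self) -> str:
        names: dict[int, str] = {i: self.labels[i] for i in range(self.n_leaves)}
        height: dict[int, float] = {i: 0.0 for i in range(self.n_leaves)}
        for i, (a, b, h, _) in enumerate(self.merges):
            node = self.n_leaves + i
            names[node] = f"({names[a]}:{h - height[a]:.6g},{names[b]}:{h - height[b]:.6g})"
            height[node] = h
        root = self.n_leaves + len(self.merges) - 1
        return names[root] + ";"


def uncentered_correlation_distance(matrix: np.ndarray) -> np.ndarray:
    """Pairwise d(x, y) = 1 - sum(x*y) / sqrt(sum(x^2) * sum(y^2)).

    Rows with zero norm get distance 1 to everything (flagged by the caller).
    """
    m = np.asarray(matrix, dtype=float)
    norms = np.sqrt((m ** 2).sum(axis=1))
    dots = m @ m.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = dots / np.outer(norms, norms)
    d = 1.0 - sim
    zero = norms == 0
    d[zero, :] = 1.0
    d[:, zero] = 1.0
    np.fill_diagonal(d, 0.0)
    return d


def uncentered_avg_linkage(matrix, labels=None) -> ClusterTree:
    """Average-linkage agglomerative clustering under uncentered correlation.

    Lance-Williams update: d(i+j, k) = (ni*d(i,k) + nj*d(j,k)) / (ni + nj).
    """
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    if n < 2:
        raise ValueError("need at least two items to cluster")
    if labels is None:
        labels = [f"item{i}" for i in range(n)]
    flags = []
    if (np.sqrt((m ** 2).sum(axis=1)) == 0).any():
        flags.append("zero-norm-row")
    d = uncentered_correlation_distance(m)
    active = {i: (i, 1) for i in range(n)}  # slot -> (node id, size)
    big = np.inf
    dist = d.copy()
    np.fill_diagonal(dist, big)
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    slots = list(range(n))
    for _ in range(n - 1):
        sub = dist[np.ix_(slots, slots)]
        flat = np.argmin(sub)
        i_loc, j_loc = divmod(flat, len(slots))
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        si, sj = slots[i_loc], slots[j_loc]
        h = dist[si, sj]
        id_i, n_i = active[si]
        id_j, n_j = active[sj]
        a, b = sorted((id_i, id_j))
        merges.append((a, b, float(h), n_i + n_j))
        for sk in slots:
            if sk in (si, sj):
                continue
            dnew = (n_i * dist[si, sk] + n_j * dist[sj, sk]) / (n_i + n_j)
            dist[si, sk] = dist[sk, si] = dnew
        active[si] = (next_id, n_i + n_j)
        next_id += 1
        slots.remove(sj)
        del active[sj]
    return ClusterTree(n_leaves=n, merges=merges, labels=list(labels), flags=flags)
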
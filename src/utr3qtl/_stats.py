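"""Small shared statistical primitives used by more than one stage."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "inverse_normal_transform",
    "stouffer_combine",
    "ranksum_exact_p",
    "wilcoxon_two_sided",
    "quantile_normalize",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def inverse_normal_transform(values, offset: float = 0.5) -> np.ndarray:
    """Rank-based mapping onto standard-normal quantiles.

    Uses Phi^-1((rank - offset) / n) with average ranks for ties. A constant
    vector carries no rank information and is rejected.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if x.size < 2:
        raise ValueError("need at least two values to rank")
    if np.nanmax(x) == np.nanmin(x):
        raise ValueError("constant vector has no rank information")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / x.size)


def stouffer_combine(z_scores) -> tuple[float, float]:
    """Stouffer combination: Z = sum(z_i)/sqrt(k); two-sided p from |Z|."""
    z = np.asarray(z_scores, dtype=float)
    if z.size == 0:
        raise ValueError("no z-scores to combine")
    combined = z.sum() / np.sqrt(z.size)
    p = 2.0 * stats.norm.sf(abs(combined))
    return float(combined), float(p)


@lru_cache(maxsize=64)
def _u_distribution(n1: int, n2: int) -> np.ndarray:
    """Exact null pmf of the Mann-Whitney U statistic (no ties).

    Subset-sum dynamic programme: the rank sum W of the x group is the sum of
    an n1-subset of ranks 1..n1+n2 chosen uniformly; U = W - n1(n1+1)/2.
    """
    total = n1 + n2
    max_w = n1 * total  # loose upper bound on the rank sum
    # ways[j][s]: subsets of size j with rank sum s, over ranks seen so far
    ways = np.zeros((n1 + 1, max_w + 1))
    ways[0, 0] = 1.0
    for r in range(1, total + 1):
        for j in range(min(r, n1), 0, -1):
            ways[j, r:] += ways[j - 1, : max_w + 1 - r]
    w_min = n1 * (n1 + 1) // 2
    pmf = ways[n1, w_min : w_min + n1 * n2 + 1]
    return pmf / pmf.sum()


def ranksum_exact_p(x, y) -> float:
    """Exact two-sided rank-sum p (tie-free samples) from the U distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    u = float(np.sum(x[:, None] > y[None, :]) + 0.5 * np.sum(x[:, None] == y[None, :]))
    pmf = _u_distribution(n1, n2)
    u_lo = min(u, n1 * n2 - u)
    # two-sided: double the tail containing the observed U (symmetric null)
    p = 2.0 * pmf[: int(np.floor(u_lo)) + 1].sum()
    return float(min(p, 1.0))


def wilcoxon_two_sided(x, y, exact_max: int = 25) -> tuple[float, float]:
    """Two-sided rank-sum test of x vs y.

    Returns (p, direction) where direction is sign(median rank shift of x).
    Exact tie-free enumeration when both groups are small and untied, else the
    normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    direction = float(np.sign(np.median(x) - np.median(y)))
    if not has_ties and x.size <= exact_max and y.size <= exact_max:
        return ranksum_exact_p(x, y), direction
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue), direction


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns to the across-column mean of order statistics.

    Ties within a column receive the average of the target values they span.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    order = np.sort(m, axis=0)
    reference = order.mean(axis=1)
    out = np.empty_like(m)
    for j in range(m.shape[1]):
        ranks = stats.rankdata(m[:, j], method="average")
        # rank r (1-based, possibly half-integral for ties) -> interpolated ref
        out[:, j] = np.interp(ranks, np.arange(1, m.shape[0] + 1), reference)
    return out
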
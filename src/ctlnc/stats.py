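"""Shared statistical primitives.

Exact tests are delegated to scipy; the test-suite checks them against
independent enumeration oracles. Benjamini-Hochberg adjustment and the
rank-based correlation used throughout are implemented here because the
surrounding code needs strict input validation (errors on constant vectors,
p-values outside (0, 1]) that the library routines do not provide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import CtlncError

__all__ = [
    "EnrichmentResult",
    "bh_adjust",
    "fisher_two_sided",
    "haldane_odds_ratio",
    "hypergeom_upper_tail",
    "sample_odds_ratio",
    "spearman_matrix",
    "spearman_rho",
    "wilcoxon_rank_sum",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One row of a Fisher / hypergeometric enrichment screen.

    ``N``/``M``/``n``/``m`` follow the usual convention: universe size,
    genes carrying the property, query-set size, and query genes carrying
    the property.
    """

    term: str
    N: int
    M: int
    n: int
    m: int
    p_raw: float
    p_adjusted: float
    method: str
    odds_ratio: float | None = None
    enrichment_ratio: float | None = None


def hypergeom_upper_tail(N: int, M: int, n: int, m: int) -> float:
    """Upper-tail P(X >= m) for X ~ Hypergeometric(N, M, n)."""
    N, M, n, m = int(N), int(M), int(n), int(m)
    if not (0 <= M <= N and 0 <= n <= N):
        raise CtlncError(f"inconsistent hypergeometric counts N={N} M={M} n={n}")
    if not (0 <= m <= min(M, n)):
        raise CtlncError(f"m={m} outside [0, min(M={M}, n={n})]")
    return float(min(1.0, sps.hypergeom.sf(m - 1, N, M, n)))


def fisher_two_sided(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table of non-negative ints.

    Returns ``(sample_odds_ratio, p)``. The two-sided p sums probabilities
    of all tables with point probability <= that of the observed table.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise CtlncError(f"not a 2x2 table of non-negative integers: {table!r}")
    _, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    return sample_odds_ratio(t), float(min(1.0, p))


def sample_odds_ratio(table) -> float:
    """Unconditional sample OR ad/bc; inf if bc=0<ad, nan if both products 0."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    num, den = a * d, b * c
    if den == 0:
        return float("nan") if num == 0 else float("inf")
    return float(num / den)


def haldane_odds_ratio(table) -> float:
    """Sample OR after adding 0.5 to every cell (display-friendly with zeros)."""
    (a, b), (c, d) = np.asarray(table, dtype=float) + 0.5
    return float((a * d) / (b * c))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise CtlncError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise CtlncError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman_rho(x, y) -> float:
    """Spearman correlation as the Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CtlncError("x and y must be equal-length vectors")
    if x.size < 3:
        raise CtlncError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise CtlncError("correlation undefined for a constant vector")
    rx, ry = _midranks(x), _midranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All pairwise Spearman correlations between rows of ``a`` and rows of ``b``.

    Both matrices share the sample axis (columns). Rows that are constant
    yield nan rather than raising, so callers can mask them.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise CtlncError("sample dimensions differ")
    ra = np.apply_along_axis(_midranks, 1, a)
    rb = np.apply_along_axis(_midranks, 1, b)

    def _standardize(r):
        r = r - r.mean(axis=1, keepdims=True)
        norm = np.sqrt((r**2).sum(axis=1, keepdims=True))
        with np.errstate(invalid="ignore", divide="ignore"):
            return r / norm

    za, zb = _standardize(ra), _standardize(rb)
    return za @ zb.T


def wilcoxon_rank_sum(
    a, b, exact_max_n: int = 20, exact_ties_max_n: int = 12
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Tie-free samples with combined size <= ``exact_max_n`` use the exact
    null distribution; tied samples up to ``exact_ties_max_n`` use exact
    permutation enumeration on mid-ranks; everything else uses the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise CtlncError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if has_ties and pooled.size <= exact_ties_max_n:
        return _wilcoxon_exact_midranks(a, b, pooled)
    method = "exact" if (pooled.size <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(1.0, res.pvalue))


def _wilcoxon_exact_midranks(a, b, pooled) -> tuple[float, float]:
    from itertools import combinations

    ranks = _midranks(pooled)
    n1, n = a.size, pooled.size
    obs = ranks[:n1].sum()
    mean = n1 * (n + 1) / 2
    count = total = 0
    dev = abs(obs - mean)
    for idx in combinations(range(n), n1):
        s = ranks[list(idx)].sum()
        total += 1
        if abs(s - mean) >= dev - 1e-9:
            count += 1
    u = obs - n1 * (n1 + 1) / 2
    return float(u), count / total
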
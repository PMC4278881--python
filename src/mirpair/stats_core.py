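"""Statistical kernels shared by every pipeline stage.

Implements the small set of nonparametric and categorical tests the
analysis relies on: average-tie ranking, Spearman rank correlation with a
t-distribution p-value (and an exact-permutation alternative for tiny n),
Benjamini-Hochberg step-up adjustment, the Mann-Whitney U test, Pearson's
chi-square for r x c tables and Fisher's exact test for 2 x 2 tables.

Conventions follow what mainstream statistics packages (SPSS, R) report by
default: no Yates continuity correction for r x c chi-square, tie-corrected
normal approximation with continuity correction for Mann-Whitney outside
the exact regime, and the point-probability ("sum of tables at most as
probable") definition of the two-sided Fisher p-value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import special, stats

__all__ = [
    "RankVector",
    "CorrelationResult",
    "TestResult",
    "rank_average_ties",
    "spearman_rho",
    "spearman_p_tapprox",
    "spearman_p_exact_perm",
    "bh_adjust",
    "mann_whitney",
    "chi_square_rxc",
    "fisher_exact_2x2",
]


@dataclass(frozen=True)
class RankVector:
    """Values together with their 1-based average-tie ranks."""

    values: np.ndarray
    ranks: np.ndarray


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation with its significance."""

    rho: float
    n: int
    p_value: float
    method: Literal["t_approx", "exact_perm"]


@dataclass(frozen=True)
class TestResult:
    """A test statistic, optional degrees of freedom and a p-value."""

    statistic: float
    df: Optional[float]
    p_value: float
    test_name: Literal["mann_whitney_u", "chi_square", "fisher_exact"]


def _as_finite_1d(values: Sequence[float], name: str = "values") -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D vector")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


def rank_average_ties(values: Sequence[float]) -> RankVector:
    """Rank a vector 1..n, assigning tied values the mean of their ranks.

    The ranks always sum to n(n+1)/2, so downstream rank statistics are
    unaffected by how ties are ordered in the input.
    """
    arr = _as_finite_1d(values)
    n = arr.size
    order = np.argsort(arr, kind="stable")
    ranks = np.empty(n, dtype=float)
    sorted_vals = arr[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        # ties spanning ranks i+1 .. j+1 all get the mean rank
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return RankVector(values=arr, ranks=ranks)


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float(rx @ ry) / denom


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of average-tie ranks."""
    xa = _as_finite_1d(x, "x")
    ya = _as_finite_1d(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("Spearman correlation requires n >= 3")
    return _rho_of_ranks(rank_average_ties(xa).ranks, rank_average_ties(ya).ranks)


def spearman_p_tapprox(rho: float, n: int) -> float:
    """Two-sided p-value for a Spearman rho via the t approximation.

    Refers t = rho * sqrt((n-2)/(1-rho^2)) to a t distribution with n-2
    degrees of freedom.  |rho| = 1 returns 0 by convention (the statistic
    diverges).
    """
    if abs(rho) > 1:
        raise ValueError("|rho| must not exceed 1")
    if n < 4:
        raise ValueError("t approximation requires n >= 4")
    if abs(rho) == 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_test(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rho with its t-approximation p-value."""
    rho = spearman_rho(x, y)
    n = len(x)
    return CorrelationResult(rho=rho, n=n, p_value=spearman_p_tapprox(rho, n), method="t_approx")


def spearman_p_exact_perm(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided permutation p-value for Spearman rho (n <= 8).

    Enumerates all n! permutations of y; p is the fraction of permutations
    whose |rho| is at least the observed |rho| (so p >= 1/n! always, and
    the identity permutation guarantees p > 0).
    """
    xa = _as_finite_1d(x, "x")
    ya = _as_finite_1d(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    n = xa.size
    if n < 3:
        raise ValueError("requires n >= 3")
    if n > 8:
        raise ValueError("exact permutation test limited to n <= 8")
    rx = rank_average_ties(xa).ranks
    ry = rank_average_ties(ya).ranks
    observed = abs(_rho_of_ranks(rx, ry))
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if abs(_rho_of_ranks(rx, ry[list(perm)])) >= observed - 1e-12:
            hits += 1
    return hits / total


def bh_adjust(p_values: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``m`` optionally sets the number of tests in the family (>= the number
    of p-values supplied); by default it is the input length.  The adjusted
    value for the i-th smallest p is min over j >= i of m * p_(j) / j,
    capped at 1.
    """
    p = _as_finite_1d(p_values, "p_values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    if m is None:
        m = k
    if m < k:
        raise ValueError("m must be at least the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(k, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _mann_whitney_exact_p(u: float, nx: int, ny: int) -> float:
    """Exact two-sided p for tie-free data by the U-count recursion."""
    # counts[u] = number of label assignments giving that U, built by the
    # standard partition recursion over Gaussian binomial coefficients
    max_u = nx * ny
    counts = np.zeros(max_u + 1, dtype=float)
    counts[0] = 1.0
    # polynomial product: prod_{i=1..nx} (1 - q^(ny+i)) / (1 - q^i)
    for i in range(1, nx + 1):
        # multiply by 1/(1 - q^i): cumulative sums with stride i
        for u_ in range(i, max_u + 1):
            counts[u_] += counts[u_ - i]
        hi = ny + i
        for u_ in range(max_u, hi - 1, -1):
            counts[u_] -= counts[u_ - hi]
    total = counts.sum()
    u_int = int(round(u))
    lower = counts[: u_int + 1].sum() / total
    upper = counts[u_int:].sum() / total
    return float(min(1.0, 2.0 * min(lower, upper)))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Mann-Whitney U test, two-sided.

    Exact enumeration when min(nx, ny) <= 8 and the pooled sample is
    tie-free; otherwise the normal approximation with tie correction and a
    0.5 continuity correction.  U counts the (x, y) pairs with x > y (ties
    counted 1/2).
    """
    xa = _as_finite_1d(x, "x")
    ya = _as_finite_1d(y, "y")
    nx, ny = xa.size, ya.size
    pooled = np.concatenate([xa, ya])
    ranks = rank_average_ties(pooled).ranks
    rx = ranks[:nx].sum()
    u = rx - nx * (nx + 1) / 2.0  # pairs with x > y, ties 1/2
    has_ties = np.unique(pooled).size < pooled.size
    if min(nx, ny) <= 8 and not has_ties:
        p = _mann_whitney_exact_p(u, nx, ny)
    else:
        mu = nx * ny / 2.0
        n = nx + ny
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        sigma_sq = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if sigma_sq <= 0:
            p = 1.0
        else:
            z = (abs(u - mu) - 0.5) / math.sqrt(sigma_sq)
            p = float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))
    return TestResult(statistic=float(u), df=None, p_value=p, test_name="mann_whitney_u")


def chi_square_rxc(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square test of independence for an r x c count table.

    No continuity correction; df = (r-1)(c-1); upper-tail p-value.  All row
    and column margins must be positive.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("table must contain non-negative finite counts")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("every row and column margin must be positive")
    expected = np.outer(rows, cols) / t.sum()
    statistic = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df=df))
    return TestResult(statistic=statistic, df=float(df), p_value=p, test_name="chi_square")


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Fisher's exact test for a 2 x 2 table, two-sided.

    The two-sided p sums the hypergeometric probabilities of every table
    with the observed margins whose point probability does not exceed that
    of the observed table (the convention SPSS and R share).  The reported
    statistic is the sample odds ratio (inf/nan for zero cells).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table must be a 2 x 2 grid of non-negative integers")
    a, b = t[0]
    c, d = t[1]
    n = a + b + c + d
    r1, c1 = a + b, a + c
    k_lo = int(max(0, r1 + c1 - n))
    k_hi = int(min(r1, c1))
    support = np.arange(k_lo, k_hi + 1)
    pmf = stats.hypergeom.pmf(support, int(n), int(c1), int(r1))
    p_obs = stats.hypergeom.pmf(int(a), int(n), int(c1), int(r1))
    p = float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = float((a * d) / (b * c)) if b * c > 0 else math.inf if a * d > 0 else math.nan
    return TestResult(statistic=odds, df=None, p_value=p, test_name="fisher_exact")
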
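"""Statistical primitives used throughout the pipeline.

Fisher's exact test, the hypergeometric enrichment tail, the exact
Wilcoxon rank-sum distribution and Benjamini-Hochberg adjustment are
implemented here directly (exact tail sums over integer combinatorics)
rather than delegated, so their behaviour on small tables is fully
specified: two-sided Fisher p-values sum the probabilities of all tables
at most as probable as the observed one, and exact paths are used for
small samples with a deterministic switch to asymptotic approximations.

All tests are two-sided unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb, sqrt
from typing import Sequence

import numpy as np
from scipy import special
from scipy.stats import rankdata

__all__ = [
    "TestResult",
    "CorrelationScreenResult",
    "fisher_exact_2x2",
    "hypergeom_enrich",
    "bh_adjust",
    "pearson",
    "spearman",
    "wilcoxon_rank_sum",
    "mpc_correlation_screen",
]

# Relative slack when deciding which table probabilities count as "at most
# as probable as observed"; guards against float round-off in the pmf.
_TWOSIDED_REL_EPS = 1e-7


@dataclass
class TestResult:
    """A test statistic with raw (and optionally adjusted) p-value."""

    statistic: float
    p_value: float
    n: int
    p_adjusted: float | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        self.p_value = min(self.p_value, 1.0)
        if self.p_adjusted is not None:
            self.p_adjusted = min(self.p_adjusted, 1.0)
            if self.p_adjusted + 1e-12 < self.p_value:
                raise ValueError("p_adjusted must be >= p_value")


@dataclass
class CorrelationScreenResult:
    """Per-gene outcome of the dual-anchor correlation screen."""

    gene_id: str
    rho_mpc1: float
    p_adj_mpc1: float
    rho_mpc2: float
    p_adj_mpc2: float
    label: str  # pos_both / neg_both / neither


# ---------------------------------------------------------------------------
# exact discrete tests
# ---------------------------------------------------------------------------


def _hypergeom_pmf_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X = k) for X ~ Hypergeom(N, K, n), as an exact rational."""
    if k < max(0, n + K - N) or k > min(K, n):
        return Fraction(0)
    return Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    The p-value sums the conditional (hypergeometric) probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's.  The statistic is the sample odds ratio
    ``(a*d)/(b*c)`` (``inf`` when ``b*c == 0`` and ``a*d > 0``).
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr != np.floor(arr)) or np.any(arr < 0):
            raise ValueError("table entries must be non-negative integers")
        arr = arr.astype(int)
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    N = a + b + c + d
    if N == 0:
        raise ValueError("empty table")
    K = a + b  # row-1 margin
    n = a + c  # col-1 margin
    p_obs = _hypergeom_pmf_exact(a, N, K, n)
    total = Fraction(0)
    cutoff = p_obs * (Fraction(10**7 + 1, 10**7))  # relative slack
    for k in range(max(0, n + K - N), min(K, n) + 1):
        pk = _hypergeom_pmf_exact(k, N, K, n)
        if pk <= cutoff:
            total += pk
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return TestResult(
        statistic=odds, p_value=float(min(total, Fraction(1))), n=N, method="fisher"
    )


def hypergeom_enrich(
    hits: int, set_size: int, universe_size: int, draw_size: int
) -> TestResult:
    """Upper-tail hypergeometric enrichment: P(X >= hits).

    ``X`` counts members of a set of ``set_size`` genes among ``draw_size``
    genes drawn without replacement from a universe of ``universe_size``.
    """
    if not (0 <= set_size <= universe_size and 0 <= draw_size <= universe_size):
        raise ValueError("inconsistent hypergeometric parameters")
    if not (0 <= hits <= min(set_size, draw_size)):
        raise ValueError("hits outside feasible range")
    total = Fraction(0)
    for k in range(hits, min(set_size, draw_size) + 1):
        total += _hypergeom_pmf_exact(k, universe_size, set_size, draw_size)
    return TestResult(
        statistic=float(hits),
        p_value=float(min(total, Fraction(1))),
        n=universe_size,
        method="hypergeom_upper",
    )


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    ``p_adj[(i)] = min_{j >= i} p[(j)] * m / j`` over the order statistics,
    which is monotone in the input order statistics and idempotent.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


def _corr_t_pvalue(r: float, n: int) -> float:
    """Two-sided p for a correlation coefficient via the t transform."""
    if n < 3:
        raise ValueError("need n >= 3 for a correlation p-value")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = r * sqrt((n - 2) / (1 - r * r))
    # survival function of Student t with n-2 df via the incomplete beta
    df = n - 2
    x = df / (df + t * t)
    p = special.betainc(df / 2.0, 0.5, x)
    return float(min(1.0, p))


def pearson(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        raise ValueError("zero variance input")
    r = float(xc @ yc) / denom
    return TestResult(statistic=r, p_value=_corr_t_pvalue(r, n), n=n, method="pearson")


def _exact_spearman_pvalue(xr: np.ndarray, yr: np.ndarray, r_obs: float) -> float:
    """Exact two-sided permutation p-value for the rank correlation (n <= 9)."""
    from itertools import permutations

    n = xr.size
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = sqrt(float(xc @ xc) * float(yc @ yc))
    perms = np.array(list(permutations(range(n))))
    rs = (yc[perms] @ xc) / denom
    return float(np.mean(np.abs(rs) >= abs(r_obs) - 1e-12))


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation (mid-ranks with tie correction).

    The coefficient is the Pearson correlation of mid-ranks.  For n <= 9
    the p-value is computed by exact enumeration of the permutation null;
    otherwise the t approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    xr = rankdata(x)
    yr = rankdata(y)
    if np.ptp(xr) == 0 or np.ptp(yr) == 0:
        raise ValueError("zero variance input")
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    rho = float(xc @ yc) / sqrt(float(xc @ xc) * float(yc @ yc))
    if n <= 9:
        p = _exact_spearman_pvalue(xr, yr, rho)
    else:
        p = _corr_t_pvalue(rho, n)
    return TestResult(statistic=rho, p_value=p, n=n, method="spearman")


# ---------------------------------------------------------------------------
# rank-sum
# ---------------------------------------------------------------------------

_ENUM_LIMIT = 20000  # full-enumeration budget for the exact rank-sum path


def _ranksum_exact_enumerate(pooled_ranks: np.ndarray, na: int, w_obs: float) -> float:
    """Exact two-sided p by enumerating every assignment of group A ranks."""
    from itertools import combinations

    n = pooled_ranks.size
    sums = np.array(
        [sum(pooled_ranks[list(idx)]) for idx in combinations(range(n), na)]
    )
    lo = np.mean(sums <= w_obs + 1e-9)
    hi = np.mean(sums >= w_obs - 1e-9)
    return float(min(1.0, 2.0 * min(lo, hi)))


def _ranksum_exact_dp(n: int, na: int, w_obs: float) -> float:
    """Exact two-sided p for untied ranks 1..n via the classic recursion."""
    # counts[j, s] = number of na-subsets of {1..i} of size j with rank sum s
    max_sum = na * n
    counts = np.zeros((na + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for i in range(1, n + 1):
        upper = min(na, i)
        for j in range(upper, 0, -1):
            counts[j, i:] += counts[j - 1, : max_sum + 1 - i]
    dist = counts[na]
    total = dist.sum()
    w = int(round(w_obs))
    lo = dist[: w + 1].sum() / total
    hi = dist[w:].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    The statistic is the rank sum W of group ``a`` over the pooled
    mid-ranks.  Exact paths: full enumeration whenever it is cheap
    (handles ties exactly), otherwise the classic no-ties recursion when
    ``min(n) <= 10``; the normal approximation with tie correction covers
    the rest.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty 1-D vectors")
    na, nb = a.size, b.size
    n = na + nb
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    w = float(ranks[:na].sum())
    has_ties = np.unique(pooled).size < n
    if comb(n, na) <= _ENUM_LIMIT:
        p = _ranksum_exact_enumerate(ranks, na, w)
        method = "ranksum_exact_enum"
    elif not has_ties and min(na, nb) <= 10:
        p = _ranksum_exact_dp(n, na, w)
        method = "ranksum_exact_dp"
    else:
        mu = na * (n + 1) / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var == 0:
            return TestResult(statistic=w, p_value=1.0, n=n, method="ranksum_normal")
        z = (w - mu) / sqrt(var)
        p = float(special.erfc(abs(z) / sqrt(2.0)))
        method = "ranksum_normal"
    return TestResult(statistic=w, p_value=p, n=n, method=method)


# ---------------------------------------------------------------------------
# transcriptome-wide dual-anchor correlation screen
# ---------------------------------------------------------------------------


def _spearman_vs_matrix(anchor: np.ndarray, mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and t-approximation p of one anchor against matrix rows."""
    n = anchor.size
    ar = rankdata(anchor)
    mr = np.apply_along_axis(rankdata, 1, mat)
    ac = ar - ar.mean()
    mc = mr - mr.mean(axis=1, keepdims=True)
    denom = np.sqrt(float(ac @ ac) * np.einsum("ij,ij->i", mc, mc))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (mc @ ac) / denom
    rho = np.where(denom == 0, 0.0, rho)
    rho = np.clip(rho, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t2 = rho * rho * df / np.maximum(1e-300, 1.0 - rho * rho)
    x = df / (df + t2)
    p = special.betainc(df / 2.0, 0.5, x)
    p = np.where(np.abs(rho) >= 1.0, 0.0, np.minimum(1.0, p))
    return rho, p


def mpc_correlation_screen(
    matrix,
    mpc1_id: str,
    mpc2_id: str,
    alpha: float = 0.01,
) -> list[CorrelationScreenResult]:
    """Correlate every gene with both anchor genes (Spearman) and classify.

    Each anchor defines one BH family over all non-anchor genes.  A gene is
    ``pos_both`` when both correlations are positive with BH-adjusted
    p < ``alpha`` for both anchors, ``neg_both`` symmetrically, otherwise
    ``neither``.  Mirrors a transcriptome-wide screen anchored on the two
    mitochondrial pyruvate carrier subunits.
    """
    genes = list(matrix.gene_ids)
    for anchor in (mpc1_id, mpc2_id):
        if anchor not in genes:
            raise ValueError(f"anchor gene {anchor!r} not in matrix")
    n = len(matrix.sample_ids)
    if n < 10:
        raise ValueError("need at least 10 samples for the correlation screen")
    tested = [g for g in genes if g not in (mpc1_id, mpc2_id)]
    mat = matrix.values.loc[tested].to_numpy(dtype=float)
    out: list[CorrelationScreenResult] = []
    rho1, p1 = _spearman_vs_matrix(
        matrix.values.loc[mpc1_id].to_numpy(dtype=float), mat
    )
    rho2, p2 = _spearman_vs_matrix(
        matrix.values.loc[mpc2_id].to_numpy(dtype=float), mat
    )
    q1 = bh_adjust(p1)
    q2 = bh_adjust(p2)
    for i, g in enumerate(tested):
        if q1[i] < alpha and q2[i] < alpha and rho1[i] > 0 and rho2[i] > 0:
            label = "pos_both"
        elif q1[i] < alpha and q2[i] < alpha and rho1[i] < 0 and rho2[i] < 0:
            label = "neg_both"
        else:
            label = "neither"
        out.append(
            CorrelationScreenResult(
                gene_id=g,
                rho_mpc1=float(rho1[i]),
                p_adj_mpc1=float(q1[i]),
                rho_mpc2=float(rho2[i]),
                p_adj_mpc2=float(q2[i]),
                label=label,
            )
        )
    return out
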
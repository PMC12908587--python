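"""Shared exact/small-sample statistics used throughout the pipeline.

Implements exact Wilcoxon rank-sum and signed-rank tests (full null
distributions via dynamic programming for small n, normal approximation
with tie correction above the exact limit), Fisher's exact test on 2x2
tables, Pearson correlation with a t-based p-value, Benjamini-Hochberg
q-values, and the alpha-diversity vs. metabolic-adaptation association
battery.
"""

from __future__ import annotations

import functools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

EXACT_LIMIT = 25


@dataclass(frozen=True)
class AssociationResult:
    """Pearson correlation between two aligned subject-level variables."""

    name_x: str
    name_y: str
    n: int
    r: float
    t: float
    p: float


# ---------------------------------------------------------------------------
# Pearson correlation


def pearson_assoc(
    x: Sequence[float],
    y: Sequence[float],
    name_x: str = "x",
    name_y: str = "y",
) -> AssociationResult:
    """Pearson r with a two-sided p from the t distribution on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("Pearson correlation requires n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return AssociationResult(name_x, name_y, n, r, math.inf, 0.0)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return AssociationResult(name_x, name_y, n, r, t, min(1.0, float(p)))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney)


@functools.lru_cache(maxsize=128)
def _ranksum_counts(n1: int, n2: int) -> np.ndarray:
    """Number of ways to choose n1 of ranks 1..n1+n2 with each rank sum.

    counts[w] = #subsets of size n1 with sum w.  DP over the generating
    function prod (1 + z*q^r).
    """
    n = n1 + n2
    max_sum = n1 * n + 1  # upper bound on achievable sum, exclusive
    dp = np.zeros((n1 + 1, max_sum), dtype=float)
    dp[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            dp[k, r:] += dp[k - 1, :-r] if r > 0 else dp[k - 1]
    return dp[n1]


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], exact_limit: int = EXACT_LIMIT
) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact (full rank-sum null distribution) when both samples fit under
    ``exact_limit`` and there are no ties; midranks with the tie-corrected
    normal approximation (continuity corrected) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n1].sum())
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and n1 <= exact_limit and n2 <= exact_limit:
        counts = _ranksum_counts(n1, n2)
        total = counts.sum()
        wi = int(round(w))
        lo = counts[: wi + 1].sum() / total
        hi = counts[wi:].sum() / total
        return min(1.0, 2.0 * min(lo, hi))
    # normal approximation with tie correction
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n - 1) * n)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return min(1.0, 2.0 * float(sps.norm.sf(z)))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


@functools.lru_cache(maxsize=128)
def _signed_rank_counts(ranks2: tuple[int, ...]) -> np.ndarray:
    """counts[w] = #sign assignments with positive doubled-rank sum w.

    ``ranks2`` are the (mid)ranks doubled so that ties yield integers.
    """
    max_sum = sum(ranks2)
    dp = np.zeros(max_sum + 1, dtype=float)
    dp[0] = 1.0
    for r in ranks2:
        dp[r:] += dp[:-r].copy()
    return dp


def wilcoxon_signed_rank(
    d: Sequence[float], exact_limit: int = EXACT_LIMIT, min_n: int = 5
) -> float:
    """Two-sided signed-rank p on paired differences.

    Zero differences are dropped (Wilcoxon's original treatment); exact
    null distribution (over sign flips, with midranks doubled to integers
    under ties) for n <= ``exact_limit``.
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    if n < min_n:
        raise ValueError(
            f"signed-rank test requires >= {min_n} nonzero differences, got {n}"
        )
    absd = np.abs(d)
    ranks = sps.rankdata(absd)
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_limit:
        ranks2 = tuple(int(round(2 * r)) for r in sorted(ranks))
        counts = _signed_rank_counts(ranks2)
        total = counts.sum()
        wi = int(round(2 * w_pos))
        lo = counts[: wi + 1].sum() / total
        hi = counts[wi:].sum() / total
        return min(1.0, 2.0 * min(lo, hi))
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(absd, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48.0
    if var == 0:
        return 1.0
    z = (abs(w_pos - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return min(1.0, 2.0 * float(sps.norm.sf(z)))


# ---------------------------------------------------------------------------
# Fisher's exact test


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric point probabilities
    no larger than that of the observed table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a 2x2 array of non-negative integers")
    if np.any(np.asarray(table, dtype=float) != t):
        raise ValueError("table entries must be integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        raise ValueError("both margins must be positive")
    rv = sps.hypergeom(n, r1, c1)
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    if p > 1.0 - 1e-9:  # accumulated pmf round-off
        p = 1.0
    return min(1.0, p)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with enforced monotonicity."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Diversity vs. adaptation association battery


def diversity_adaptation_analysis(
    alpha_pre: Sequence[float],
    alpha_delta: Sequence[float],
    adaptation_rmr: Sequence[float],
    adaptation_tdee: Sequence[float],
    min_n: int = 5,
) -> dict[str, AssociationResult]:
    """The four alpha-diversity vs. energy-adaptation correlations.

    Each pair is analysed on its own complete cases (pairwise deletion);
    the retained n is logged and carried in every result.
    """
    arrays = {
        "alpha_pre": np.asarray(alpha_pre, dtype=float),
        "alpha_delta": np.asarray(alpha_delta, dtype=float),
        "adaptation_rmr": np.asarray(adaptation_rmr, dtype=float),
        "adaptation_tdee": np.asarray(adaptation_tdee, dtype=float),
    }
    n_all = {a.size for a in arrays.values()}
    if len(n_all) != 1:
        raise ValueError("all inputs must be aligned to the same subjects")
    pairs = [
        ("alpha_pre", "adaptation_rmr"),
        ("alpha_pre", "adaptation_tdee"),
        ("alpha_delta", "adaptation_rmr"),
        ("alpha_delta", "adaptation_tdee"),
    ]
    out: dict[str, AssociationResult] = {}
    for nx, ny in pairs:
        x, y = arrays[nx], arrays[ny]
        mask = np.isfinite(x) & np.isfinite(y)
        n = int(mask.sum())
        if n < min_n:
            raise ValueError(
                f"{nx} vs {ny}: only {n} complete cases (need >= {min_n})"
            )
        logger.info("associating %s vs %s on %d complete cases", nx, ny, n)
        out[f"{nx}__{ny}"] = pearson_assoc(x[mask], y[mask], nx, ny)
    return out
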
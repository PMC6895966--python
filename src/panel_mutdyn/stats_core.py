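"""Exact small-sample statistics shared by every downstream stage.

All tests are two-sided.  The cohorts this pipeline targets are tiny
(n <= 19 patients, a handful of mutations per sample), so exactness and
platform-independent determinism matter more than asymptotic speed:

* Fisher's exact test uses the point-probability two-sided definition
  (sum of hypergeometric probabilities of all tables, margins fixed, whose
  point probability does not exceed the observed table's), the convention
  of R ``fisher.test`` and maftools.  Point-probability comparisons carry a
  relative slack of 1e-7 so floating-point rounding cannot flip a boundary
  table in or out of the sum.
* The hypergeometric upper tail is accumulated in log-space.
* Rank tests take the exact enumeration path whenever the sample sizes
  permit it and there are no ties, falling back to the mid-rank normal
  approximation with continuity correction otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats as _sps
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "fisher_exact_2x2",
    "hypergeometric_upper_tail",
    "bh_fdr",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
]

#: Relative tolerance for "point probability <= observed" comparisons.
POINT_PROB_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows are levels of one factor, columns of the other."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for count in (self.a, self.b, self.c, self.d):
            if count < 0 or int(count) != count:
                raise ValueError(f"counts must be non-negative integers, got {count}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided test; fields not meaningful for a test are None."""

    p_value: float
    statistic: float | None = None
    odds_ratio: float | None = None
    n_effective: int | None = None


def _as_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    return ContingencyTable2x2(int(arr[0, 0]), int(arr[0, 1]), int(arr[1, 0]), int(arr[1, 1]))


@lru_cache(maxsize=1_000_000)
def _fisher_cached(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = _sps.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + POINT_PROB_RTOL)].sum())
    p = min(p, 1.0)
    ad, bc = a * d, b * c
    if bc == 0:
        odds = math.inf if ad > 0 else math.nan  # nan: undefined (both products 0)
    else:
        odds = ad / bc
    return p, odds


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The odds ratio is the unconditional sample estimate (a*d)/(b*c):
    infinite when only b*c vanishes, NaN (undefined) when both diagonal
    products are zero.
    """
    t = _as_table(table)
    p, odds = _fisher_cached(t.a, t.b, t.c, t.d)
    return TestResult(p_value=p, odds_ratio=odds)


def hypergeometric_upper_tail(k: int, set_size: int, draws: int, universe: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(universe, set_size, draws).

    This is the classic over-representation p-value for an overlap of *k*
    genes between a query of size *draws* and a gene set of size *set_size*
    inside a *universe*.  Summed in log-space for numerical stability.
    """
    if not (0 <= k <= min(set_size, draws) <= universe):
        raise ValueError(
            f"inconsistent counts: k={k}, set_size={set_size}, draws={draws}, "
            f"universe={universe}"
        )
    if set_size > universe or draws > universe:
        raise ValueError("set size and draw count cannot exceed the universe")
    if k == 0:
        return 1.0
    support = np.arange(k, min(set_size, draws) + 1)
    logp = _sps.hypergeom.logpmf(support, universe, set_size, draws)
    return float(min(1.0, math.exp(logsumexp(logp))))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min over j with p_(j) >= p_(i) of m * p_(j) / rank(j), clipped
    to [0, 1]; a single p-value maps to itself.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    return np.minimum(q, 1.0)


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_threshold: int = 25
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration of rank assignments when ``min(|x|, |y|) <=
    exact_threshold`` and the pooled values are tie-free; otherwise the
    mid-rank normal approximation with continuity and tie correction.  The
    statistic reported is U for the first group.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([xa, ya])
    if np.unique(pooled).size == 1:
        return TestResult(p_value=1.0, statistic=float(xa.size * ya.size) / 2.0)
    exact = min(xa.size, ya.size) <= exact_threshold and not _has_ties(pooled)
    res = _sps.mannwhitneyu(
        xa,
        ya,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(p_value=float(min(res.pvalue, 1.0)), statistic=float(res.statistic))


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped before ranking; with no surviving pairs the
    test is vacuous (p = 1, n_effective = 0).  Exact sign enumeration for
    n <= 15 without tied absolute differences, else the normal approximation
    with continuity correction.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size != ya.size:
        raise ValueError(f"paired samples differ in length: {xa.size} vs {ya.size}")
    diffs = xa - ya
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        return TestResult(p_value=1.0, statistic=None, n_effective=0)
    exact = n <= 15 and not _has_ties(np.abs(diffs))
    res = _sps.wilcoxon(
        diffs,
        alternative="two-sided",
        method="exact" if exact else "approx",
        correction=not exact,
    )
    return TestResult(
        p_value=float(min(res.pvalue, 1.0)),
        statistic=float(res.statistic),
        n_effective=n,
    )
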
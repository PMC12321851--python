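"""Shared statistical primitives for the co-abundance pipeline.

Every hypothesis test used downstream funnels through this module so that
conventions (two-sided alternatives, tie handling, exact-vs-approximate
switchover) are fixed in one place and recorded in the returned
:class:`TestResult`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "TestMethod",
    "spearman",
    "spearman_exact_p",
    "bh_adjust",
    "wilcoxon_ranksum",
    "paired_t",
    "anova_oneway",
    "rank_auc",
]

#: Significance-star ladder used throughout the figures-facing reports.
STAR_LEVELS = (0.05, 0.01, 0.001, 0.0001)


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star annotation (ns for p >= 0.05)."""
    if p is None or not np.isfinite(p):
        return "na"
    stars = sum(p < level for level in STAR_LEVELS)
    return "*" * stars if stars else "ns"


class TestMethod(str, Enum):
    wilcoxon_ranksum = "wilcoxon_ranksum"
    paired_t = "paired_t"
    anova_oneway = "anova_oneway"


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample (or paired / k-sample) hypothesis test.

    ``statistic`` and ``p_value`` are NaN when the test is undefined on the
    input (zero variance, degenerate group sizes); ``undefined`` is then set
    so callers can distinguish "no evidence" from "not computable".
    """

    statistic: float
    p_value: float
    method: TestMethod
    n1: int
    n2: int
    exact: bool = False
    undefined: bool = False
    warning: str | None = None

    @property
    def stars(self) -> str:
        return "na" if self.undefined else significance_stars(self.p_value)


def _as_1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size and not np.all(np.isfinite(a)):
        raise ValueError("input contains non-finite values")
    return a


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties and t-approximation p.

    Returns ``(rho, p)``. A constant input vector makes the correlation
    undefined; ``(nan, nan)`` is returned rather than a silent zero.
    """
    x, y = _as_1d(x), _as_1d(y)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman requires two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    rho, p = sps.spearmanr(x, y)
    return (float(rho), float(p))


def spearman_exact_p(x, y) -> float:
    """Exact two-sided permutation p-value for Spearman rho (n <= 8).

    Enumerates all n! orderings of ``y``; intended as an oracle for the
    t-approximation, not for production use.
    """
    x, y = _as_1d(x), _as_1d(y)
    n = x.size
    if n > 8:
        raise ValueError("exact permutation p only supported for n <= 8")
    rho_obs, _ = spearman(x, y)
    if math.isnan(rho_obs):
        return math.nan
    rx = sps.rankdata(x)
    count = total = 0
    for perm in itertools.permutations(sps.rankdata(y)):
        r = np.corrcoef(rx, perm)[0, 1]
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Output is in the input order, with the cumulative-minimum monotonicity
    enforcement applied from the largest rank downward, clipped at 1.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumeration of all group assignments."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1 = a.size
    w_obs = ranks[:n1].sum()
    mu = n1 * (pooled.size + 1) / 2.0
    dev = abs(w_obs - mu)
    count = total = 0
    for idx in itertools.combinations(range(pooled.size), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= dev - 1e-12:
            count += 1
    return count / total


def wilcoxon_ranksum(a, b, mode: str = "exact_if_small") -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``mode='exact_if_small'`` enumerates the exact null when the combined
    sample size is at most 12 and the data are tie-free; otherwise (and in
    ``mode='approx'``) the normal approximation with tie and continuity
    correction is used. The route taken is recorded in ``TestResult.exact``.
    """
    a, b = _as_1d(a), _as_1d(b)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    if np.ptp(pooled) == 0:
        return TestResult(w, 1.0, TestMethod.wilcoxon_ranksum, a.size, b.size,
                          exact=False, warning="all observations tied; zero rank variance")
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = mode == "exact_if_small" and pooled.size <= 12 and not has_ties
    if use_exact:
        p = _exact_ranksum_p(a, b)
        return TestResult(w, p, TestMethod.wilcoxon_ranksum, a.size, b.size, exact=True)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult(w, float(res.pvalue), TestMethod.wilcoxon_ranksum,
                      a.size, b.size, exact=False)


def paired_t(diffs=None, *, x=None, y=None) -> TestResult:
    """Two-sided paired t-test, on differences or on paired vectors.

    t = mean(d) / (sd(d)/sqrt(n)) with n-1 degrees of freedom. Zero variance
    of the differences yields an undefined-statistic marker, not an error.
    """
    if diffs is None:
        d = _as_1d(x) - _as_1d(y)
    else:
        d = _as_1d(diffs)
    n = d.size
    if n < 3:
        return TestResult(math.nan, math.nan, TestMethod.paired_t, n, n,
                          undefined=True, warning="fewer than 3 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        return TestResult(math.nan, math.nan, TestMethod.paired_t, n, n,
                          undefined=True, warning="zero variance of differences")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2 * sps.t.sf(abs(t), df=n - 1)
    return TestResult(float(t), float(p), TestMethod.paired_t, n, n, exact=False)


def anova_oneway(*groups) -> TestResult:
    """Ordinary one-way ANOVA across two or more groups."""
    arrays = [_as_1d(g) for g in groups]
    if len(arrays) < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    pooled = np.concatenate(arrays)
    n1 = arrays[0].size
    n2 = arrays[1].size
    if np.ptp(pooled) == 0:
        return TestResult(math.nan, math.nan, TestMethod.anova_oneway, n1, n2,
                          undefined=True, warning="zero total variance")
    f, p = sps.f_oneway(*arrays)
    if not np.isfinite(f):
        return TestResult(math.nan, math.nan, TestMethod.anova_oneway, n1, n2,
                          undefined=True, warning="degenerate within-group variance")
    return TestResult(float(f), float(p), TestMethod.anova_oneway, n1, n2)


def rank_auc(scores_pos, scores_neg) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 P(tie), via the rank statistic.

    Equals the trapezoidal area under the empirical ROC curve.
    """
    pos, neg = _as_1d(scores_pos), _as_1d(scores_neg)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score vectors must be non-empty")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))
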
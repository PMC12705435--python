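"""Shared statistical kernels: BH, Welch gene-set test, Pearson, Wilcoxon, logistic fit."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

import statsmodels.api as sm


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    testable: bool = True


def welch_set_test(member_stats, nonmember_stats) -> WelchResult:
    """Two-sample Welch t-test of the ranking statistic, set members vs the rest.

    This is the parametric arm of the dual significance gate: does the set's
    mean correlation differ from the complement's, allowing unequal variances.
    """
    a = np.asarray(member_stats, dtype=float)
    b = np.asarray(nonmember_stats, dtype=float)
    if a.size < 2 or b.size < 2:
        return WelchResult(np.nan, np.nan, np.nan, testable=False)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / a.size + vb / b.size
    if se2 == 0:
        return WelchResult(0.0, float(a.size + b.size - 2), 1.0)
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(min(p, 1.0)))


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    defined: bool = True


def pearson_age_correlation(values, ages) -> CorrelationResult:
    """Pearson r of a per-donor quantity against age, two-sided t-based p.

    Zero variance on either side leaves r undefined (flagged, not thrown).
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(ages, dtype=float)
    n = x.size
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, n, defined=False)
    r, p = scipy.stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n)


@dataclass
class WilcoxonResult:
    w: float  # rank-sum of the first group
    p: float
    exact: bool


def _rank_sum(a_ranks) -> float:
    return float(np.sum(a_ranks))


def wilcoxon_rank_sum(a, b) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact null enumeration when n_A + n_B <= 12 and there are no ties
    (two-sided p doubles the smaller tail, capped at 1); otherwise the
    normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    ranks = scipy.stats.rankdata(pooled)
    w_obs = _rank_sum(ranks[:na])
    no_ties = np.unique(pooled).size == n
    if n <= 12 and no_ties:
        sums = np.array(
            [sum(idx) + na for idx in combinations(range(n), na)], dtype=float
        )  # rank sums over all C(n, na) assignments (ranks are 1..n)
        lo = np.mean(sums <= w_obs)
        hi = np.mean(sums >= w_obs)
        p = min(1.0, 2.0 * min(lo, hi))
        return WilcoxonResult(w_obs, float(p), exact=True)
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return WilcoxonResult(w_obs, float(res.pvalue), exact=False)


@dataclass
class LogisticFitResult:
    coef: float
    intercept: float
    se: float
    p: float
    converged: bool
    separated: bool

    @property
    def testable(self) -> bool:
        return self.converged and not self.separated


def logistic_fit(x, y, max_iter: int = 25, tol: float = 1e-8) -> LogisticFitResult:
    """Univariate logistic regression of a binary response on one covariate.

    IRLS maximization of the binomial likelihood with a Wald z test on the
    slope.  Perfect separation (the covariate splits the classes) is flagged
    and the fit reported not-testable instead of returning a runaway slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be coded 0/1")
    if (y == 0).sum() < 2 or (y == 1).sum() < 2:
        raise ValueError("need >=2 observations per class")
    if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
        return LogisticFitResult(np.nan, np.nan, np.nan, np.nan, True, True)
    X = sm.add_constant(x)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        fit = model.fit(maxiter=max_iter, tol=tol)
    except Exception:
        return LogisticFitResult(np.nan, np.nan, np.nan, np.nan, False, False)
    converged = bool(getattr(fit, "converged", True))
    coef = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(se) or se > 1e4:
        # SE blow-up is the numerical face of quasi-separation
        return LogisticFitResult(coef, float(fit.params[0]), se, np.nan, converged, True)
    z = coef / se
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return LogisticFitResult(coef, float(fit.params[0]), se, float(p), converged, False)
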
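"""Shared statistical primitives.

Thin, contract-enforcing wrappers around scipy / statsmodels so every
stage uses one implementation of Welch's t, Fisher's exact test,
Benjamini-Hochberg adjustment and Pearson correlation.
"""

from __future__ import annotations

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .models import StatResult


def welch_t(x, y) -> StatResult:
    """Welch two-sample t-test (unequal variances), two-sided.

    Both groups need >= 2 observations. If both groups have zero variance
    and equal means the test is vacuous and p = 1 by convention; zero
    variance otherwise is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires at least 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return StatResult(statistic=0.0, p_value=1.0, df=float(x.size + y.size - 2))
        raise ValueError("zero variance in both groups with unequal means")
    if vx == 0.0 or vy == 0.0:
        raise ValueError("zero variance in one group")
    res = scipy.stats.ttest_ind(x, y, equal_var=False)
    return StatResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      df=float(res.df))


def fisher_exact(table, alternative: str = "two-sided") -> StatResult:
    """Fisher's exact test on a 2x2 contingency table.

    Two-sided p sums hypergeometric probabilities of tables at least as
    extreme as observed (scipy's definition). ``alternative`` may be
    'greater'/'less' for one-sided enrichment tests.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact requires a 2x2 table")
    if (t < 0).any():
        raise ValueError("negative cell in contingency table")
    if t.sum() == 0:
        raise ValueError("all-zero contingency table")
    odds, p = scipy.stats.fisher_exact(t, alternative=alternative)
    return StatResult(statistic=float(odds), p_value=float(p),
                      extra={"table": t.tolist()})


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson(x, y) -> StatResult:
    """Pearson correlation with two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson requires equal-length vectors of size >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = scipy.stats.pearsonr(x, y)
    return StatResult(statistic=float(r), p_value=float(p), df=float(x.size - 2),
                      estimate=float(r))
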
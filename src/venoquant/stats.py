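"""Nonparametric group statistics and scan-rescan reliability.

All comparisons are two-sided and judged at a nominal alpha = .01 with no
formal multiplicity correction (many related outcomes are tested, so the
nominal level is kept deliberately strict instead). Exact small-sample
distributions are used where feasible:

* Mann-Whitney U — exact when both groups have n <= 12 and there are no
  ties, otherwise the normal approximation with tie correction.
* Wilcoxon signed rank — zero differences dropped; exact when n <= 15 with
  untied |differences|, otherwise normal approximation.
* Fisher's exact test — two-sided hypergeometric sum.
* Spearman rank correlation — midrank ties; full permutation p for n <= 9,
  t approximation otherwise.
* ICC — two-way random-effects, absolute-agreement, single-measure
  (the standard scan-rescan form), from the ANOVA mean squares of a
  subjects x sessions decomposition.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "ALPHA",
    "mann_whitney",
    "fisher_exact",
    "spearman",
    "wilcoxon_signed_rank",
    "icc",
]

ALPHA = 0.01  # nominal two-tailed significance level

_EXACT_MW_MAX_N = 12
_EXACT_WILCOXON_MAX_N = 15
_EXACT_SPEARMAN_MAX_N = 9


@dataclass
class ComparisonResult:
    statistic: float
    pvalue: float
    n: tuple[int, ...]
    test: str
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        if not 0 <= self.pvalue <= 1:
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def mann_whitney(group_a, group_b) -> ComparisonResult:
    """Mann-Whitney rank-sum U test, two-sided."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    exact = a.size <= _EXACT_MW_MAX_N and b.size <= _EXACT_MW_MAX_N and not _has_ties(pooled)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact" if exact else "asymptotic")
    return ComparisonResult(
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        n=(a.size, b.size),
        test="mann-whitney-exact" if exact else "mann-whitney-normal",
    )


def fisher_exact(table) -> ComparisonResult:
    """Two-sided Fisher exact test on a 2x2 count table."""
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("need a 2x2 table of non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("a table margin is zero")
    res = sps.fisher_exact(t, alternative="two-sided")
    return ComparisonResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n=(int(t[0].sum()), int(t[1].sum())),
        test="fisher-exact",
    )


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rho = np.corrcoef(rx, ry)[0, 1]
    return float(rho)


def spearman(x, y) -> ComparisonResult:
    """Spearman rank correlation with midrank ties.

    Permutation p-value (all n! relabelings) for n <= 9, Student-t
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _spearman_rho(rx, ry)
    if n <= _EXACT_SPEARMAN_MAX_N:
        perms = np.array(list(itertools.permutations(ry)))
        rxc = rx - rx.mean()
        denom = np.sqrt((rxc**2).sum() * ((perms - perms.mean(axis=1, keepdims=True)) ** 2).sum(axis=1))
        rhos = (perms - perms.mean(axis=1, keepdims=True)) @ rxc / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        test = "spearman-permutation"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * sps.t.sf(abs(t), df=n - 2))
        test = "spearman-t"
    return ComparisonResult(statistic=rho, pvalue=min(p, 1.0), n=(n,), test=test)


def wilcoxon_signed_rank(pre, post) -> ComparisonResult:
    """Wilcoxon signed-rank test on paired samples, two-sided.

    Zero differences are dropped before ranking (recorded in the test name
    via the effective n).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size:
        raise ValueError("paired samples must have equal length")
    d = post - pre
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    exact = d.size <= _EXACT_WILCOXON_MAX_N and not _has_ties(np.abs(d))
    res = sps.wilcoxon(d, alternative="two-sided", method="exact" if exact else "approx",
                       correction=not exact)
    return ComparisonResult(
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        n=(d.size,),
        test="wilcoxon-exact" if exact else "wilcoxon-normal",
    )


def icc(ratings: np.ndarray) -> float:
    """Two-way random-effects absolute-agreement single-measure ICC.

    ``ratings`` is subjects x sessions (no missing values, >= 3 subjects,
    >= 2 sessions). Computed from the two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    where MSR, MSC, MSE are the subject, session and residual mean squares,
    n the subject count and k the session count.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[0] < 3 or r.shape[1] < 2:
        raise ValueError("need a subjects x sessions matrix, >=3 subjects, >=2 sessions")
    if not np.all(np.isfinite(r)):
        raise ValueError("missing values are not supported")
    n, k = r.shape
    grand = r.mean()
    if np.allclose(r, grand):
        raise ValueError("zero total variance")
    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((r - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))
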
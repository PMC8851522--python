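"""Shared nonparametric tests: Mann-Whitney, Spearman, chi-square.

Thin, opinionated wrappers over scipy.stats that fix the conventions used
throughout the package: two-sided p-values, exact Mann-Whitney enumeration
for small tie-free samples, optional Yates correction for 2x2 tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DataError

# Combined sample size at or below which the exact Mann-Whitney null
# distribution is enumerated (auto mode, tie-free data only).
EXACT_MW_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided hypothesis test."""

    statistic: float
    p: float
    method: str
    n: tuple[int, ...]

    def __iter__(self):  # allow `stat, p = result`
        return iter((self.statistic, self.p))


def mann_whitney(a, b, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test.

    Parameters
    ----------
    a, b : array-like
        The two independent samples.
    mode : {"auto", "exact", "normal_approx"}
        ``exact`` enumerates the permutation null (requires tie-free data in
        scipy's implementation to be exact); ``normal_approx`` uses the normal
        approximation with tie and continuity corrections. ``auto`` picks
        exact when ``len(a)+len(b) <= 12`` and there are no ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("mann_whitney requires non-empty groups")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        method = "exact" if (pooled.size <= EXACT_MW_MAX_N and not has_ties) else "asymptotic"
    elif mode == "exact":
        method = "exact"
    elif mode == "normal_approx":
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue),
                      f"mann-whitney ({method})", (a.size, b.size))


def spearman(a, b) -> TestResult:
    """Spearman rank correlation (average ranks) with t-approximation p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DataError("spearman requires paired vectors of equal length")
    if a.size < 3:
        raise DataError("spearman requires n >= 3")
    if np.unique(a).size == 1 or np.unique(b).size == 1:
        raise DataError("spearman undefined: zero rank variance in one vector")
    rho, p = sps.spearmanr(a, b)
    return TestResult(float(rho), float(p), "spearman", (a.size,))


def chi_square(table, correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    ``correction=True`` applies the Yates continuity correction (2x2 only,
    per scipy semantics). Default is no correction.
    """
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise DataError("chi_square requires nonnegative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DataError("chi_square: zero row or column marginal")
    res = sps.chi2_contingency(table, correction=correction)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "chi-square", tuple(int(n) for n in table.sum(axis=1)))
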
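"""Statistical battery for the QA cohort: Shapiro-Wilk normality screening,
independent-sample t-tests between technique groups, Wilcoxon signed-rank
tests between paired planning/synthetic metrics, Spearman rank correlation
between image-quality metrics and gamma passing rates, and Bonferroni
multiplicity correction.  All alternatives are two-sided; significance is
declared at p < 0.05 after correction.

These are thin, contract-enforcing wrappers over scipy.stats: they add the
input validation, zero-difference handling and not-applicable flagging the
pipeline relies on, and return uniform result records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

ALPHA_DEFAULT = 0.05


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n: int
    p_adjusted: Optional[float] = None
    significant: Optional[bool] = None
    not_applicable: bool = False
    note: str = ""

    def adjust(self, family_size: int, alpha: float = ALPHA_DEFAULT) -> "TestResult":
        """Bonferroni-adjust this result within a family of tests."""
        if self.not_applicable:
            return self
        self.p_adjusted = bonferroni([self.p_value], family_size)[0]
        self.significant = bool(self.p_adjusted < alpha)
        return self


@dataclass
class CorrelationResult:
    coefficient: float          # Spearman r_s in [-1, 1]
    p_value: float
    n: int
    pair: tuple = ("", "")      # (metric label, gamma criterion label)


def _finite_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def shapiro_wilk(sample) -> TestResult:
    """Shapiro-Wilk normality test; requires 3 <= n <= 5000 and nonzero
    variance."""
    x = _finite_array(sample, "sample")
    if not (3 <= x.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: normality test undefined")
    res = sps.shapiro(x)
    return TestResult("shapiro_wilk", float(res.statistic), float(res.pvalue),
                      n=int(x.size))


def independent_t_test(a, b) -> TestResult:
    """Two-sided independent-sample t-test between two groups."""
    xa = _finite_array(a, "a")
    xb = _finite_array(b, "b")
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.ptp(xa) == 0 and np.ptp(xb) == 0:
        raise ValueError("degenerate variance in both groups")
    res = sps.ttest_ind(xa, xb)
    return TestResult("independent_t", float(res.statistic), float(res.pvalue),
                      n=int(xa.size + xb.size))


#: sample size above which the Wilcoxon p-value switches from exact
#: enumeration to the tie-corrected normal approximation
WILCOXON_EXACT_MAX_N = 25


def wilcoxon_signed_rank(paired_a, paired_b) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped before ranking.  When every difference is
    zero the comparison carries no information and the result is flagged
    not-applicable rather than raising — matching how an all-tied DVH
    metric (e.g. V110% = 0 on both plans) is reported.  Exact enumeration
    is used up to n = 25 nonzero differences, the normal approximation with
    tie correction beyond.
    """
    xa = _finite_array(paired_a, "paired_a")
    xb = _finite_array(paired_b, "paired_b")
    if xa.size != xb.size:
        raise ValueError("paired samples must have equal length")
    diffs = xa - xb
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return TestResult("wilcoxon_signed_rank", np.nan, np.nan, n=0,
                          not_applicable=True, note="all differences zero")
    method = "exact" if nonzero.size <= WILCOXON_EXACT_MAX_N else "approx"
    res = sps.wilcoxon(xa, xb, zero_method="wilcox", method=method,
                       correction=False)
    return TestResult("wilcoxon_signed_rank", float(res.statistic),
                      float(res.pvalue), n=int(nonzero.size))


def spearman(x, y, pair: tuple = ("", "")) -> CorrelationResult:
    """Spearman rank correlation with average-rank tie handling."""
    xa = _finite_array(x, "x")
    ya = _finite_array(y, "y")
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("constant input: rank correlation undefined")
    res = sps.spearmanr(xa, ya)
    return CorrelationResult(float(res.statistic), float(res.pvalue),
                             n=int(xa.size), pair=pair)


def bonferroni(p_values: Sequence[float], family_size: Optional[int] = None):
    """Bonferroni adjustment: ``min(1, p * m)`` with m defaulting to the
    number of p-values supplied."""
    ps = np.asarray(list(p_values), dtype=float)
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(ps) if family_size is None else int(family_size)
    if m < 1:
        raise ValueError("family size must be >= 1")
    return list(np.minimum(1.0, ps * m))
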
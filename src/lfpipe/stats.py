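"""Group statistics used by the analyses: unpaired t-tests (Welch by
default), Holm–Šidák step-down correction, and Fisher's exact test.

Thin, validated wrappers over scipy.stats and statsmodels that return a
uniform :class:`TestResult` and handle the degenerate zero-variance cases
explicitly. Tests are two-sided throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

__all__ = ["TestResult", "unpaired_ttest", "holm_sidak", "fisher_exact"]


@dataclass
class TestResult:
    __test__ = False  # not a pytest collection target

    statistic: float
    p: float
    method: str
    df: float | None = None
    p_adjusted: float | None = None


def unpaired_ttest(a, b, variant: str = "welch") -> TestResult:
    """Two-sided unpaired t-test; ``variant`` is ``"welch"`` or ``"pooled"``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown variant {variant!r}")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return TestResult(statistic=0.0, p=1.0, df=float(a.size + b.size - 2),
                              method=f"unpaired t ({variant})")
        warnings.warn("zero variance in both samples with unequal means: p -> 0")
        return TestResult(statistic=np.inf if a.mean() > b.mean() else -np.inf,
                          p=0.0, df=float(a.size + b.size - 2),
                          method=f"unpaired t ({variant})")
    res = spstats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue),
                      df=float(res.df), method=f"unpaired t ({variant})")


def holm_sidak(pvals) -> np.ndarray:
    """Holm–Šidák step-down adjusted p values, returned in the input order.

    Sorting the raw p ascending, the i-th (1-based) is adjusted to
    1 − (1 − p_i)^(m − i + 1), with a running maximum enforcing step-down
    monotonicity.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, adj, _, _ = multipletests(p, method="holm-sidak")
    return adj


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2×2 contingency table.

    p is the sum of hypergeometric probabilities of all tables with the same
    margins whose probability does not exceed the observed table's.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    odds, p = spstats.fisher_exact(t, alternative="two-sided")
    return TestResult(statistic=float(odds), p=float(p),
                      method="Fisher exact (two-sided)")
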
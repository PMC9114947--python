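"""Group comparisons and correlations for per-population summaries.

Thin, validated layer over :mod:`scipy.stats`: Welch two-sample t with a
Wilcoxon-Mann-Whitney fallback chosen by a Shapiro-Wilk normality screen,
classical paired t, and Pearson / Spearman correlations.  All tests are
two-sided; no multiple-testing correction is applied by default (a
Bonferroni helper exists for users who want one).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "two_sample_test",
    "paired_t_test",
    "pearson_correlation",
    "spearman_correlation",
    "bonferroni",
    "TestResult",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    method: str


def _asarray(x, name: str, min_n: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if len(arr) < min_n:
        raise ValidationError(f"{name} needs at least {min_n} values, got {len(arr)}")
    if np.isnan(arr).any():
        raise ValidationError(f"{name} contains missing values")
    return arr


def two_sample_test(x, y, force: str = "auto", alpha_normality: float = 0.05) -> TestResult:
    """Two-sided two-sample location test.

    ``force="t"`` runs Welch's unequal-variance t, ``force="wilcoxon"``
    the Wilcoxon-Mann-Whitney test (exact when sample sizes permit).  In
    ``auto`` mode a Shapiro-Wilk screen on each group (at
    ``alpha_normality``) picks Welch when both groups pass, otherwise the
    rank test; the chosen branch is logged.
    """
    x = _asarray(x, "x", 2)
    y = _asarray(y, "y", 2)
    if force not in ("auto", "t", "wilcoxon"):
        raise ValidationError(f"force must be auto/t/wilcoxon, got {force!r}")

    if np.ptp(x) == 0.0 and np.ptp(y) == 0.0:
        if x[0] == y[0]:
            warnings.warn("both groups constant and equal; p = 1", stacklevel=2)
            return TestResult(statistic=0.0, p=1.0, method="degenerate")
        # constant but different: rank test is still defined
        force = "wilcoxon" if force == "auto" else force

    method = force
    if force == "auto":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # shapiro warns for tiny n
            normal = (stats.shapiro(x).pvalue > alpha_normality
                      and stats.shapiro(y).pvalue > alpha_normality)
        method = "t" if normal else "wilcoxon"
        logger.info("two_sample_test auto-selected %s (Shapiro screen at alpha=%g)",
                    method, alpha_normality)

    if method == "t":
        res = stats.ttest_ind(x, y, equal_var=False)
        return TestResult(statistic=float(res.statistic), p=float(res.pvalue), method="welch_t")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue),
                      method="wilcoxon_mann_whitney")


def paired_t_test(x, y) -> TestResult:
    """Classical two-sided paired t-test on matched value pairs."""
    x = _asarray(x, "x", 2)
    y = _asarray(y, "y", 2)
    if len(x) != len(y):
        raise ValidationError(f"paired samples differ in length ({len(x)} vs {len(y)})")
    d = x - y
    if np.ptp(d) == 0.0:
        raise ValidationError("differences have zero variance; paired t undefined")
    res = stats.ttest_rel(x, y)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue), method="paired_t")


def pearson_correlation(x, y) -> TestResult:
    """Pearson r with two-sided t-based p on n-2 degrees of freedom."""
    x = _asarray(x, "x", 3)
    y = _asarray(y, "y", 3)
    if len(x) != len(y):
        raise ValidationError(f"samples differ in length ({len(x)} vs {len(y)})")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValidationError("constant input; correlation undefined")
    res = stats.pearsonr(x, y)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue), method="pearson")


def spearman_correlation(x, y) -> TestResult:
    """Spearman rank correlation (two-sided)."""
    x = _asarray(x, "x", 3)
    y = _asarray(y, "y", 3)
    if len(x) != len(y):
        raise ValidationError(f"samples differ in length ({len(x)} vs {len(y)})")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValidationError("constant input; correlation undefined")
    res = stats.spearmanr(x, y)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue), method="spearman")


def bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Bonferroni-adjusted p-values (off by default everywhere upstream)."""
    p = np.asarray(p_values, dtype=float)
    return np.clip(p * len(p), 0.0, 1.0)
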
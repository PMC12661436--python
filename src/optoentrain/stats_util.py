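"""Shared statistical primitives: the normality-gated paired test and
normality checks used across the stimulation-response, spike-field and
behavior stages."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

#: significance level of the normality gate (fixed, independent of test alpha)
NORMALITY_ALPHA = 0.05


def lilliefors_pvalue(x: np.ndarray) -> float:
    """Lilliefors (KS with estimated mean/sd) p-value for normality of *x*."""
    x = np.asarray(x, dtype=float)
    if x.size < 4 or np.ptp(x) == 0:
        return float("nan")
    return float(lilliefors(x, dist="norm")[1])


def anderson_darling_rejects(x: np.ndarray, alpha: float = NORMALITY_ALPHA) -> bool:
    """True if the Anderson-Darling test rejects normality of *x* at *alpha*."""
    res = stats.anderson(np.asarray(x, dtype=float), dist="norm", method="interpolate")
    return bool(res.pvalue < alpha)


def differences_look_normal(d: np.ndarray, alpha: float = NORMALITY_ALPHA) -> bool:
    """Both Lilliefors and Anderson-Darling fail to reject normality of *d*."""
    d = np.asarray(d, dtype=float)
    if np.ptp(d) == 0:
        return False  # degenerate; normality tests undefined
    lp = lilliefors_pvalue(d)
    if np.isnan(lp) or lp < alpha:
        return False
    return not anderson_darling_rejects(d, alpha)


def normality_gated_paired_test(x, y, alpha: float = 0.05) -> tuple[str, float, float]:
    """Paired comparison with the test chosen by normality of the differences.

    Computes d = x - y; if both Lilliefors and Anderson-Darling fail to reject
    normality of d at the 5% level, a paired t-test is used, otherwise the
    Wilcoxon signed-rank test. Returns (test_used, statistic, two-sided p).
    All-zero differences short-circuit to ("degenerate", 0, 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 5:
        raise ValueError("need >= 5 pairs")
    d = x - y
    if np.all(d == 0):
        return "degenerate", 0.0, 1.0
    if differences_look_normal(d):
        stat, p = stats.ttest_rel(x, y)
        return "paired_t", float(stat), float(p)
    stat, p = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided")
    return "wilcoxon_signed_rank", float(stat), float(p)
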
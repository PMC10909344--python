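"""Across-run statistical battery: SMA slope test, variance test, t-test,
residual-vs-detection-difference diagnostic.

The central test is a standardized major axis (SMA) regression of the
sampled metric on the full-population metric across replicate runs, with
a one-sample test of the slope against 1 (perfect agreement).  SMA is
the appropriate line here because both axes are measured with error and
no direction of prediction is privileged; its slope is
``sign(r) * sd(y) / sd(x)``.

The one-sample slope test transforms to residual and axis scores at the
hypothesised slope ``b0`` — ``y - b0*x`` and ``y + b0*x`` — whose
correlation is zero iff the SMA slope equals ``b0``; the squared
correlation maps to an F(1, n-2) statistic.  The 95% CI inverts the same
pivot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "SlopeTestResult",
    "sma_fit_and_test",
    "variance_test",
    "delta_p_group_test",
    "residual_bias_diagnostic",
    "BONFERRONI_THRESHOLD",
]

#: Family-wise significance threshold for the ten-test battery
#: (0.05 / 10); summaries print raw p-values alongside it.
BONFERRONI_THRESHOLD = 0.005


@dataclass
class SlopeTestResult:
    """SMA slope estimate with CI and the one-sample test against ``test_slope``."""

    slope_hat: float
    ci_low: float
    ci_high: float
    r: float        # residual-vs-axis correlation at the test slope
    p_value: float
    f_stat: float
    n: int
    r_xy: float     # plain correlation of x and y
    test_slope: float


def _clean_pairs(x: np.ndarray, y: np.ndarray, *extra: np.ndarray) -> tuple[np.ndarray, ...]:
    """Pairwise-delete rows with any non-finite entry."""
    arrays = [np.asarray(a, dtype=float) for a in (x, y, *extra)]
    mask = np.logical_and.reduce([np.isfinite(a) for a in arrays])
    return tuple(a[mask] for a in arrays)


def sma_fit_and_test(
    x: np.ndarray, y: np.ndarray, test_slope: float = 1.0, alpha: float = 0.05
) -> SlopeTestResult:
    """SMA fit of ``y`` on ``x`` and a one-sample test of the slope.

    Non-finite pairs are deleted before fitting.  Raises on fewer than
    three pairs or zero variance on either axis.
    """
    x, y = _clean_pairs(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"SMA needs at least 3 finite pairs, got {n}")
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("SMA undefined: zero variance on an axis")
    r_xy = float(np.corrcoef(x, y)[0, 1])
    sign = -1.0 if r_xy < 0 else 1.0
    slope = sign * sy / sx

    # one-sample test: correlation of residual and axis scores at b0
    resid = y - test_slope * x
    axis = y + test_slope * x
    sr, sa = np.std(resid, ddof=1), np.std(axis, ddof=1)
    if sr == 0 or sa == 0:
        r_rf = 0.0
    else:
        r_rf = float(np.corrcoef(resid, axis)[0, 1])
    df = n - 2
    denom = max(1.0 - r_rf**2, np.finfo(float).tiny)
    f_stat = r_rf**2 * df / denom
    p = float(sps.f.sf(f_stat, 1, df))

    # CI by inverting the pivot (standard allometry construction)
    f_crit = sps.f.ppf(1.0 - alpha, 1, df)
    big_b = f_crit * (1.0 - r_xy**2) / df
    ci_low = slope * (np.sqrt(big_b + 1.0) - np.sqrt(big_b))
    ci_high = slope * (np.sqrt(big_b + 1.0) + np.sqrt(big_b))
    if slope < 0:
        ci_low, ci_high = ci_high, ci_low
    return SlopeTestResult(
        slope_hat=float(slope), ci_low=float(ci_low), ci_high=float(ci_high),
        r=r_rf, p_value=p, f_stat=float(f_stat), n=n, r_xy=r_xy,
        test_slope=float(test_slope),
    )


def variance_test(sample_values: np.ndarray, reference_values: np.ndarray) -> tuple[float, float]:
    """Fligner-Killeen homogeneity-of-variances test (median-centred).

    Returns ``(chi-squared statistic, p-value)`` with df = 1 for the
    two-group comparison of sampled metric values against the
    full-population values.
    """
    a = np.asarray(sample_values, dtype=float)
    b = np.asarray(reference_values, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("variance test needs at least 2 finite values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("variance test degenerate: both groups constant")
    stat, p = sps.fligner(a, b)
    return float(stat), float(p)


def delta_p_group_test(
    delta_p_control: np.ndarray, delta_p_biased: np.ndarray
) -> tuple[float, float, float]:
    """Welch two-sample t-test on CJS detection differences.

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom.
    """
    a, b = (np.asarray(v, dtype=float) for v in (delta_p_control, delta_p_biased))
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t-test needs at least 2 finite values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("t-test degenerate: zero variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def residual_bias_diagnostic(
    full_values: np.ndarray,
    sampled_values: np.ndarray,
    abs_delta_p: np.ndarray,
) -> tuple[float, float, float]:
    """Can the CJS detection difference flag badly-biased runs?

    Step 1: ordinary least-squares of the sampled metric on the full
    metric; keep residuals.  Step 2: OLS of those residuals on the
    absolute CJS detection difference.  Returns ``(slope, p, adjusted
    R^2)`` of step 2; a positive slope means larger detection differences
    go with larger metric errors.
    """
    full, sampled, adp = _clean_pairs(full_values, sampled_values, abs_delta_p)
    if len(full) < 3:
        raise ValueError("diagnostic needs at least 3 finite triples")
    if np.ptp(full) == 0 or np.ptp(adp) == 0:
        raise ValueError("diagnostic degenerate: a regressor is constant")
    step1 = sm.OLS(sampled, sm.add_constant(full)).fit()
    resid = step1.resid
    step2 = sm.OLS(resid, sm.add_constant(adp)).fit()
    return float(step2.params[1]), float(step2.pvalues[1]), float(step2.rsquared_adj)
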
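"""Repeat-simulation comparison statistics.

When the same target settings are optimized repeatedly (the algorithm is
stochastic, so repeats differ), the resulting metric values form a sample.
Three statistics summarize how well the repeats recover a reference value:

* a 95% confidence interval of the repeat mean (t-based by default);
* the *scaled deviation*: distance from the reference value to the nearest
  CI bound, as a percentage of the spread of the reference values, signed
  negative when the recreated values lie below the reference;
* an accuracy/precision regression of repeat means on reference values:
  accuracy holds when the slope CI contains 1 and the intercept CI contains
  0; precision is the fit's r-squared.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ComparisonRow",
    "repeat_ci",
    "scaled_deviation",
    "accuracy_precision",
    "AccuracyPrecision",
    "comparison_rows",
]


def repeat_ci(
    values, level: float = 0.95, use_t: bool = True
) -> tuple[float, float, float]:
    """Mean and confidence interval of repeat values: mean +/- q * sd / sqrt(n).

    ``q`` is the t quantile with n-1 degrees of freedom by default, or the
    normal quantile with ``use_t=False``.  Needs at least two values;
    constant values give a zero-width interval.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 repeat values for a confidence interval")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    p = 1.0 - (1.0 - level) / 2.0
    q = stats.t.ppf(p, x.size - 1) if use_t else stats.norm.ppf(p)
    half = q * sd / np.sqrt(x.size)
    return mean, mean - half, mean + half


def scaled_deviation(
    real: float, ci_low: float, ci_high: float, spread: float
) -> float:
    """Signed distance from the real value to the nearest CI bound, % of spread.

    Zero when the real value lies inside the interval.  Negative when the
    recreated values lie *below* the real value (real above ci_high),
    positive when they lie above it.  Invariant under common rescaling of
    all four arguments.
    """
    if spread <= 0:
        raise ValueError("spread must be positive")
    if ci_low <= real <= ci_high:
        return 0.0
    if real > ci_high:
        return -100.0 * (real - ci_high) / spread
    return 100.0 * (ci_low - real) / spread


@dataclass(frozen=True)
class AccuracyPrecision:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    contains_1: bool  # slope CI contains 1 => accurate scaling
    contains_0: bool  # intercept CI contains 0 => accurate offset
    r_squared: float  # precision


def accuracy_precision(
    real_values, sim_means, level: float = 0.95
) -> AccuracyPrecision:
    """OLS of repeat means on reference values, with accuracy flags.

    Requires at least three pairs and a non-degenerate predictor.  With
    ``sim_means`` identical to ``real_values`` the fit is exactly slope 1,
    intercept 0, r-squared 1 and both flags hold.
    """
    x = np.asarray(real_values, dtype=float)
    y = np.asarray(sim_means, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 (real, simulated) pairs")
    if np.ptp(x) == 0:
        raise ValueError("reference values are constant; regression undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=1.0 - level)
    icpt = (float(ci[0][0]), float(ci[0][1]))
    slope = (float(ci[1][0]), float(ci[1][1]))
    return AccuracyPrecision(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_ci=slope,
        intercept_ci=icpt,
        contains_1=slope[0] <= 1.0 <= slope[1],
        contains_0=icpt[0] <= 0.0 <= icpt[1],
        r_squared=float(res.rsquared),
    )


@dataclass(frozen=True)
class ComparisonRow:
    """One metric in one stratum/class: reference vs repeat summary."""

    metric: str
    label: str
    real: float
    mean: float
    ci_low: float
    ci_high: float
    deviation_pct: float


def comparison_rows(
    metric: str,
    real_by_label: dict[str, float],
    repeats_by_label: dict[str, list[float]],
    level: float = 0.95,
) -> list[ComparisonRow]:
    """Comparison table for one metric across strata/class labels.

    The scaled deviation of every row uses the spread (max - min) of the
    reference values across all labels, making deviations comparable between
    metrics measured in different units.
    """
    reals = np.array([real_by_label[k] for k in real_by_label], dtype=float)
    spread = float(np.ptp(reals))
    rows = []
    for label, real in real_by_label.items():
        mean, lo, hi = repeat_ci(repeats_by_label[label], level=level)
        dev = scaled_deviation(real, lo, hi, spread) if spread > 0 else 0.0
        rows.append(
            ComparisonRow(
                metric=metric,
                label=label,
                real=float(real),
                mean=mean,
                ci_low=lo,
                ci_high=hi,
                deviation_pct=dev,
            )
        )
    return rows
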
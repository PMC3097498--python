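"""Method-validation statistics: calibration, %RSD, and precision ANOVA.

The precision analysis is a balanced one-way ANOVA grouping recovery
replicates by day: the within-day mean square (WMS) estimates repeatability,
the between-day mean square (BMS) picks up day-to-day drift, and their
ratio F = BMS/WMS is compared with the upper-alpha critical value of the
F distribution to judge intermediate precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationFit",
    "RecoveryPanel",
    "PrecisionVerdict",
    "fit_calibration",
    "percent_rsd",
    "anova_precision",
    "f_critical",
    "precision_verdict",
]


@dataclass(frozen=True)
class CalibrationFit:
    """Ordinary least-squares line through calibration standards."""

    slope: float
    intercept: float
    r_squared: float
    range_low: float
    range_high: float
    n_points: int

    def predict_area(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


def fit_calibration(concentrations: Sequence[float], areas: Sequence[float]) -> CalibrationFit:
    """Least-squares linear regression of detector response on concentration.

    Requires at least three distinct concentrations. ``r_squared`` is the
    squared Pearson correlation; for a response with zero variance the
    fit is exact and r² is reported as 1.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(areas, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and areas must be equal-length 1-D vectors")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    sxy = float(((x - xbar) * (y - ybar)).sum())
    syy = float(((y - ybar) ** 2).sum())
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    r_squared = 1.0 if syy == 0.0 else min(1.0, sxy**2 / (sxx * syy))
    return CalibrationFit(
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        range_low=float(x.min()),
        range_high=float(x.max()),
        n_points=int(x.size),
    )


def percent_rsd(values: Sequence[float]) -> float:
    """Relative standard deviation: 100 * sample SD (n-1) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for %RSD")
    mean = v.mean()
    if mean == 0.0:
        raise ValueError("%RSD undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


@dataclass(frozen=True)
class RecoveryPanel:
    """Days x replicates recovery matrix with its one-way ANOVA summary.

    ``values`` has one row per day. ``f_statistic`` is None when the
    within-day mean square is zero (F undefined, never infinity).
    """

    values: np.ndarray
    spike_level: float | None
    day_means: np.ndarray
    day_rsd_percent: np.ndarray
    grand_mean: float
    wms: float
    bms: float
    f_statistic: float | None
    df_between: int
    df_within: int

    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    @property
    def mean_recovery_percent(self) -> float | None:
        """Mean amount found as a percentage of the amount added."""
        if self.spike_level is None:
            return None
        return 100.0 * self.grand_mean / self.spike_level


def anova_precision(values: np.ndarray, spike_level: float | None = None) -> RecoveryPanel:
    """Balanced one-way ANOVA of a days x replicates recovery matrix.

    Parameters
    ----------
    values : array-like, shape (n_days, n_replicates)
        Amount-found values, one row per day.
    spike_level : float, optional
        Amount added; enables the mean-recovery accuracy summary.

    Notes
    -----
    BMS = n_rep * sum((day mean - grand mean)^2) / (d - 1) and
    WMS = sum over days of within-day squared deviations / (d * (n_rep - 1));
    the between- and within-day sums of squares always add up to the total
    corrected sum of squares.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 days and >= 2 replicates per day")
    if not np.all(np.isfinite(v)):
        raise ValueError("recovery values must be finite")
    d, r = v.shape
    day_means = v.mean(axis=1)
    grand = float(v.mean())
    wss = float(((v - day_means[:, None]) ** 2).sum())
    bss = float(r * ((day_means - grand) ** 2).sum())
    wms = wss / (d * (r - 1))
    bms = bss / (d - 1)
    f_stat = bms / wms if wms > 0.0 else None
    return RecoveryPanel(
        values=v,
        spike_level=spike_level,
        day_means=day_means,
        day_rsd_percent=np.array([percent_rsd(row) for row in v]),
        grand_mean=grand,
        wms=wms,
        bms=bms,
        f_statistic=f_stat,
        df_between=d - 1,
        df_within=d * (r - 1),
    )


def f_critical(df1: int, df2: int, alpha: float) -> float:
    """Upper-``alpha`` quantile of the F(df1, df2) distribution."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(stats.f.isf(alpha, df1, df2))


@dataclass(frozen=True)
class PrecisionVerdict:
    """Outcome of the intermediate-precision F test.

    ``passed`` is None when F is undefined (indeterminate verdict).
    """

    passed: bool | None
    f_statistic: float | None
    f_crit: float
    alpha: float
    narrative: str


def precision_verdict(panel: RecoveryPanel, alpha: float = 0.05) -> PrecisionVerdict:
    """Judge intermediate precision: pass iff F < critical F.

    A pass means the between-day mean square is statistically
    indistinguishable from the within-day mean square at level ``alpha``.
    """
    crit = f_critical(panel.df_between, panel.df_within, alpha)
    if panel.f_statistic is None:
        return PrecisionVerdict(
            passed=None,
            f_statistic=None,
            f_crit=crit,
            alpha=alpha,
            narrative=(
                "Within-day mean square is zero: F is undefined and the "
                "precision verdict is indeterminate."
            ),
        )
    passed = panel.f_statistic < crit
    rel = "below" if passed else "at or above"
    narrative = (
        f"F = {panel.f_statistic:.2f} is {rel} the critical "
        f"F({panel.df_between}, {panel.df_within}) = {crit:.2f} at alpha = {alpha:g}: "
        + (
            "no significant difference between within-day and between-day "
            "variability (good intermediate precision)."
            if passed
            else "between-day variability is significantly larger than "
            "within-day variability."
        )
    )
    return PrecisionVerdict(
        passed=passed, f_statistic=panel.f_statistic, f_crit=crit, alpha=alpha, narrative=narrative
    )
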
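"""Five-year trend score and its confidence interval.

The trend T is five times the ordinary-least-squares slope of the normalized
status time series over the assessment window, clamped to [-1, +1]. The 95%
confidence interval uses the slope's standard error scaled the same way,
with the paper-of-record's coarse t multiplier of 3 (an approximation to
t(0.975, 3 df) ~ 3.182 at five points), giving bounds 5t +/- 15 se.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from . import _flags as F
from .errors import DegenerateAbscissaError

#: Window length the trend is scaled by (T = WINDOW_SCALE * slope).
WINDOW_SCALE = 5.0

#: Coarse two-tailed 95% t multiplier at 3 degrees of freedom.
T_MULTIPLIER = 3.0


@dataclass
class TrendResult:
    T: float
    slope_t: float
    se: float
    T_lower: float
    T_upper: float
    n_points: int
    clamped: bool = False
    flags: list[str] = field(default_factory=list)


def _clamp(v: float) -> float:
    return max(-1.0, min(1.0, v))


def trend_ci_halfwidth(se: float) -> float:
    """Half-width of the 95% CI on the trend score: 5 * 3 * se."""
    if se < 0:
        raise ValueError("standard error must be non-negative")
    return WINDOW_SCALE * T_MULTIPLIER * se


def fit_trend(points: pd.DataFrame, min_trend_points: int = 3) -> TrendResult:
    """Fit the trend score to (year, x) pairs.

    Parameters
    ----------
    points
        Columns ``year`` and ``x`` (normalized status); at most one point
        per year.
    min_trend_points
        Below this count no slope is fit: T = 0 with ``NO_TREND_DATA`` and a
        degenerate (0, 0) interval, the stated missing-history rule.

    Raises
    ------
    DegenerateAbscissaError
        If two or more points share a single year value.
    """
    pts = points.dropna(subset=["x"]).sort_values("year")
    n = len(pts)
    if n >= 2 and pts["year"].nunique() == 1:
        raise DegenerateAbscissaError(int(pts["year"].iloc[0]))
    if pts["year"].duplicated().any():
        raise ValueError("duplicate years in trend input")
    if n < min_trend_points:
        return TrendResult(
            T=0.0, slope_t=0.0, se=0.0, T_lower=0.0, T_upper=0.0,
            n_points=n, flags=[F.NO_TREND_DATA],
        )

    fit = stats.linregress(pts["year"].to_numpy(float), pts["x"].to_numpy(float))
    t = float(fit.slope)
    se = float(fit.stderr)
    if math.isnan(se):  # exact fit through <3 points cannot happen here, be safe
        se = 0.0

    raw_T = WINDOW_SCALE * t
    T = _clamp(raw_T)
    half = trend_ci_halfwidth(se)
    raw_lo, raw_hi = raw_T - half, raw_T + half
    lo, hi = _clamp(raw_lo), _clamp(raw_hi)

    flags: list[str] = []
    clamped = T != raw_T
    if clamped:
        flags.append(F.TREND_CLAMPED)
    if lo != raw_lo or hi != raw_hi:
        flags.append(F.CI_CLAMPED)
    return TrendResult(
        T=T, slope_t=t, se=se, T_lower=lo, T_upper=hi,
        n_points=n, clamped=clamped, flags=flags,
    )
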
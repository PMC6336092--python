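"""Outlier screening, reference-point selection, present-status normalization.

The present status of a service at a site is its indicator value divided by
the reference point: the maximum indicator value observed across all compared
sites over the assessment window, after screening outlying observations.
Screening pools the per-service sample over all sites and window years and
drops values more than k sample standard deviations from the pooled mean
(k = 2 by default), in a single pass.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _flags as F
from .errors import ReferenceUndefinedError

OBS_COLUMNS = ["site_id", "year", "value"]


@dataclass(frozen=True)
class ReferencePoint:
    """The normalization ceiling X_R for one service, with provenance."""

    service_id: str
    X_R: float
    source_site: Optional[str]
    source_year: Optional[int]
    window: tuple[int, int]
    override: bool = False


@dataclass
class ScreeningResult:
    retained: pd.DataFrame
    excluded: pd.DataFrame
    mean: float
    sd: float
    flags: list[str] = field(default_factory=list)


def screen_outliers(values: pd.DataFrame, k: float) -> ScreeningResult:
    """Single-pass screening of the pooled per-service sample.

    Parameters
    ----------
    values
        Columns ``site_id, year, value``: all observations of one service
        across all sites and window years.
    k
        Multiplier of the sample standard deviation (ddof=1).

    Notes
    -----
    With fewer than two values no screening is possible: everything is
    retained and ``NO_SCREENING`` is flagged. A zero standard deviation
    (all values equal) excludes nothing. There is no re-screening after
    exclusion.
    """
    values = values.reset_index(drop=True)
    n = len(values)
    if n < 2:
        return ScreeningResult(
            retained=values,
            excluded=values.iloc[0:0],
            mean=float(values["value"].mean()) if n else math.nan,
            sd=math.nan,
            flags=[F.NO_SCREENING],
        )
    v = values["value"].to_numpy(dtype=float)
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        mask = np.zeros(n, dtype=bool)
    else:
        mask = np.abs(v - mean) > k * sd
    return ScreeningResult(
        retained=values[~mask].reset_index(drop=True),
        excluded=values[mask].reset_index(drop=True),
        mean=mean,
        sd=sd,
    )


def reference_point(
    retained: pd.DataFrame,
    service_id: str,
    window: tuple[int, int],
    override: Optional[float] = None,
) -> ReferencePoint:
    """Select X_R = max retained value, with reproducible tie-breaking.

    Ties on the maximum are resolved to the earliest year, then the
    lexicographically first site id, so provenance is deterministic.
    A positive ``override`` short-circuits selection (fixed user-supplied
    reference, e.g. a pre-degradation ideal).

    Raises
    ------
    ReferenceUndefinedError
        If no retained observation is positive (all zero or missing).
    """
    if override is not None:
        if not override > 0:
            raise ReferenceUndefinedError(service_id)
        return ReferencePoint(service_id, float(override), None, None, window, True)

    obs = retained.dropna(subset=["value"])
    if obs.empty or not (obs["value"] > 0).any():
        raise ReferenceUndefinedError(service_id)
    x_r = float(obs["value"].max())
    at_max = obs[obs["value"] == x_r].sort_values(["year", "site_id"])
    top = at_max.iloc[0]
    return ReferencePoint(
        service_id=service_id,
        X_R=x_r,
        source_site=str(top["site_id"]),
        source_year=int(top["year"]),
        window=window,
    )


def present_status(X: Optional[float], ref: ReferencePoint) -> tuple[float, list[str]]:
    """Normalize an indicator value by the reference point: x = X / X_R.

    Returns ``(nan, [NO_DATA])`` when the value is missing. The ratio is not
    clamped: a retained evaluation-year value cannot exceed X_R by
    construction, and an excluded one is reported as-is (the caller flags
    ``OUTLIER_EVAL_YEAR``).
    """
    if X is None or (isinstance(X, float) and math.isnan(X)):
        return math.nan, [F.NO_DATA]
    return float(X) / ref.X_R, []
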
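"""Composite scores: near-term future status, service score, sustainability.

Given present status x in [0, 1], trend T in [-1, 1] and pressure-resilience
PR in [-1, 1], the near-term projection is

    x_F = (1 + beta*T + (1 - beta)*PR) * x,

the service score is the mean of present and projected status, I = (x + x_F)/2
(reported on a 0-100 scale), and the sustainability score is the relative
change S = (x_F - x)/x. Absent clamping, S reduces algebraically to
beta*T + (1 - beta)*PR, so |S| <= 1 always.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from . import _flags as F
from .config import ReportScale

_IDENTITY_TOL = 1e-9


@dataclass
class ScoreSet:
    """All scores of one (site, service) cell."""

    site_id: str
    service_id: str
    x: float = math.nan
    T: float = math.nan
    T_lower: float = math.nan
    T_upper: float = math.nan
    PR: float = math.nan
    x_F: float = math.nan
    I: float = math.nan
    S: float = math.nan  # stored as a fraction; printed as a percent
    flags: list[str] = field(default_factory=list)


def _is_na(v: Optional[float]) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def future_status(
    x: float, T: float, PR: float, beta: float
) -> tuple[float, list[str]]:
    """Project status five years out; clamp into [0, 1] with a flag.

    The multiplier 1 + beta*T + (1-beta)*PR lies in [0, 2] for in-range
    arguments, so the raw projection is never negative but can exceed the
    reference-point ceiling; values above 1 are clamped and flagged.
    """
    if _is_na(x):
        return math.nan, [F.NO_DATA]
    raw = (1.0 + beta * T + (1.0 - beta) * PR) * x
    if raw > 1.0:
        return 1.0, [F.CLAMPED_FUTURE]
    if raw < 0.0:  # only reachable with out-of-range T or PR
        return 0.0, [F.CLAMPED_FUTURE]
    return raw, []


def service_score(
    x: float, x_F: float, report_scale: ReportScale = ReportScale.percent100
) -> float:
    """I = (x + x_F) / 2, times 100 on the percent scale. NA propagates."""
    if _is_na(x) or _is_na(x_F):
        return math.nan
    i = (x + x_F) / 2.0
    if report_scale == ReportScale.percent100:
        i *= 100.0
    return i


def sustainability(x: float, x_F: float) -> tuple[float, list[str]]:
    """S = (x_F - x) / x; undefined (NA, X_ZERO) when the status is zero."""
    if _is_na(x) or _is_na(x_F):
        return math.nan, []
    if x == 0.0:
        return math.nan, [F.X_ZERO]
    return (x_F - x) / x, []


def score_service(
    site_id: str,
    service_id: str,
    x: float,
    trend_T: float,
    pr: Optional[float],
    beta: float,
    report_scale: ReportScale = ReportScale.percent100,
    trend_ci: tuple[float, float] = (math.nan, math.nan),
    extra_flags: Optional[list[str]] = None,
) -> ScoreSet:
    """Compose the full score cell from the stage outputs.

    A missing present status yields an all-NA cell flagged ``NO_DATA``.
    A missing PR is defaulted to 0 (flag ``PR_DEFAULTED``) so the projection
    reflects the trend alone. When no clamping occurred the identity
    S = beta*T + (1-beta)*PR is asserted to 1e-9.
    """
    flags = list(extra_flags or [])
    if _is_na(x):
        if F.NO_DATA not in flags:
            flags.append(F.NO_DATA)
        return ScoreSet(site_id=site_id, service_id=service_id, flags=flags)

    if pr is None or _is_na(pr):
        pr_eff = 0.0
        if F.PR_DEFAULTED not in flags:
            flags.append(F.PR_DEFAULTED)
        pr_out = math.nan
    else:
        pr_eff = float(pr)
        pr_out = pr_eff

    x_f, f_flags = future_status(x, trend_T, pr_eff, beta)
    flags += [fl for fl in f_flags if fl not in flags]
    i = service_score(x, x_f, report_scale)
    s, s_flags = sustainability(x, x_f)
    flags += [fl for fl in s_flags if fl not in flags]

    if F.CLAMPED_FUTURE not in flags and not _is_na(s):
        expected = beta * trend_T + (1.0 - beta) * pr_eff
        assert abs(s - expected) <= _IDENTITY_TOL, (
            f"sustainability identity violated at ({site_id}, {service_id}): "
            f"{s} vs {expected}"
        )

    return ScoreSet(
        site_id=site_id,
        service_id=service_id,
        x=x,
        T=trend_T,
        T_lower=trend_ci[0],
        T_upper=trend_ci[1],
        PR=pr_out,
        x_F=x_f,
        I=i,
        S=s,
        flags=flags,
    )
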
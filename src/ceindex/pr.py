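"""Pressure-resilience scoring of environmental factors.

Each environmental factor acting on a service scores in [-1, +1]: negative
when its state pressures the service, positive when it supports resilience.
Quantitative factors (e.g. dissolved-oxygen concentration) interpolate
linearly between a -1 anchor and a +1 anchor; qualitative factors (e.g.
blue-tide occurrence, ground stability) score +/- a fixed magnitude, 0.5 by
default, half the weight of a measured factor. The service-level PR score is
the unweighted mean of the scored factors.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

from . import _flags as F
from .config import Direction, FactorDefinition, FactorKind


@dataclass(frozen=True)
class FactorScore:
    factor_id: str
    service_id: str
    site_id: str
    score: Optional[float]  # None when the state is unknown/missing
    basis: str  # "quantitative" | "qualitative" | "missing"


def quantitative_factor_score(value: float, f: FactorDefinition) -> Optional[float]:
    """Piecewise-linear score of a measured factor state.

    For ``increasing_good``: -1 at or below ``lo_threshold``, +1 at or above
    ``hi_threshold``, linear in between (the dissolved-oxygen model with
    anchors 2 and 6 mg/L scores -0.5 at 3 mg/L). ``decreasing_good`` mirrors
    the line. NaN values score as missing (None).
    """
    if f.kind != FactorKind.quantitative:
        raise ValueError(f"factor {f.factor_id!r} is not quantitative")
    if value is None or math.isnan(value):
        return None
    frac = (float(value) - f.lo_threshold) / (f.hi_threshold - f.lo_threshold)
    score = max(-1.0, min(1.0, 2.0 * frac - 1.0))
    if f.direction == Direction.decreasing_good:
        score = -score
    return score


def qualitative_factor_score(state: str, f: FactorDefinition) -> Optional[float]:
    """+/- the factor's magnitude on an observed state; unknown -> None."""
    if f.kind != FactorKind.qualitative:
        raise ValueError(f"factor {f.factor_id!r} is not qualitative")
    if state == "positive":
        return +f.qualitative_magnitude
    if state == "negative":
        return -f.qualitative_magnitude
    if state in ("unknown", "", None):
        return None
    raise ValueError(f"unrecognized qualitative state {state!r}")


def score_factor(
    f: FactorDefinition,
    site_id: str,
    value: Optional[float] = None,
    state: Optional[str] = None,
) -> FactorScore:
    """Score one observed factor state against its definition."""
    if f.kind == FactorKind.quantitative:
        s = None if value is None else quantitative_factor_score(value, f)
        basis = "quantitative" if s is not None else "missing"
    else:
        s = qualitative_factor_score(state, f)
        basis = "qualitative" if s is not None else "missing"
    return FactorScore(
        factor_id=f.factor_id, service_id=f.service_id,
        site_id=site_id, score=s, basis=basis,
    )


def aggregate_pr(scores: Iterable[FactorScore]) -> tuple[Optional[float], list[str]]:
    """Unweighted mean of the scored factors of one (site, service).

    Unknown factors are excluded (absence of information is not evidence of
    neutrality) and flagged. If nothing could be scored the PR is None with
    ``NO_PR``; downstream the projection then uses PR = 0 and flags
    ``PR_DEFAULTED``, so the cell reflects trend only.
    """
    flags: list[str] = []
    vals = []
    for s in scores:
        if s.score is None:
            if F.FACTOR_UNKNOWN not in flags:
                flags.append(F.FACTOR_UNKNOWN)
        else:
            vals.append(s.score)
    if not vals:
        return None, flags + [F.NO_PR]
    return sum(vals) / len(vals), flags


def factor_diagnostics(
    scores: Iterable[FactorScore], threshold: float = 0.0
) -> list[str]:
    """Factors needing countermeasures: score below ``threshold``.

    Sorted ascending by score (worst first), ties lexicographic by id —
    the machine form of the per-service radar chart.
    """
    flagged = [s for s in scores if s.score is not None and s.score < threshold]
    flagged.sort(key=lambda s: (s.score, s.factor_id))
    return [s.factor_id for s in flagged]
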
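"""End-to-end assessment: screening -> reference -> status/trend/PR -> scores.

The pipeline never silently drops a declared (site, service) pair: every
cell yields a :class:`~ceindex.scoring.ScoreSet`, possibly all-NA with
explanatory flags, together with the full provenance needed for audit
(retained and excluded observations, the reference point and its source,
the trend fit, and each factor score).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import _flags as F
from .config import FactorKind, FactorYears, ValidatedConfig
from .errors import SchemaError
from .pr import FactorScore, aggregate_pr, score_factor
from .scoring import ScoreSet, score_service
from .status import (
    ReferencePoint,
    ScreeningResult,
    present_status,
    reference_point,
    screen_outliers,
)
from .trend import TrendResult, fit_trend


@dataclass
class CellResult:
    """Full provenance of one (site, service) score cell."""

    site_id: str
    service_id: str
    ref: ReferencePoint
    X_eval: Optional[float]
    trend: Optional[TrendResult]
    factor_scores: list[FactorScore]
    scores: ScoreSet
    retained: pd.DataFrame  # this site's retained in-window observations
    excluded: pd.DataFrame


@dataclass
class AssessmentResult:
    config: ValidatedConfig
    reference_points: dict[str, ReferencePoint]
    screenings: dict[str, ScreeningResult]
    cells: dict[tuple[str, str], CellResult] = field(default_factory=dict)

    def cell(self, site_id: str, service_id: str) -> CellResult:
        from .errors import UnknownPairError

        try:
            return self.cells[(site_id, service_id)]
        except KeyError:
            raise UnknownPairError(site_id, service_id) from None

    @property
    def score_sets(self) -> list[ScoreSet]:
        return [c.scores for c in self.cells.values()]


def _check_ids(cfg: ValidatedConfig, indicators: pd.DataFrame,
               factors: pd.DataFrame) -> None:
    known_sites = set(cfg.site_ids)
    known_services = set(cfg.service_ids)
    for df, what in ((indicators, "indicator"), (factors, "factor")):
        if df.empty:
            continue
        bad_sites = sorted(set(df["site_id"]) - known_sites)
        if bad_sites:
            raise SchemaError(f"{what} data references undeclared site(s) {bad_sites}")
        bad_services = sorted(set(df["service_id"]) - known_services)
        if bad_services:
            raise SchemaError(
                f"{what} data references undeclared service(s) {bad_services}"
            )
    if not factors.empty:
        known = {(f.service_id, f.factor_id) for f in cfg.conceptual_model.factors}
        pairs = set(zip(factors["service_id"], factors["factor_id"]))
        bad = sorted(pairs - known)
        if bad:
            raise SchemaError(f"factor data references undeclared factor(s) {bad}")


def _factor_scores_for(
    cfg: ValidatedConfig,
    factors: pd.DataFrame,
    site_id: str,
    service_id: str,
) -> list[FactorScore]:
    ass = cfg.assessment
    fdefs = cfg.conceptual_model.for_service(service_id)
    sub = factors[
        (factors["site_id"] == site_id) & (factors["service_id"] == service_id)
    ]
    out: list[FactorScore] = []
    for f in fdefs:
        obs = sub[sub["factor_id"] == f.factor_id]
        if ass.factor_years == FactorYears.evaluation_year:
            obs = obs[obs["year"] == ass.evaluation_year]
        else:
            lo, hi = ass.window
            obs = obs[(obs["year"] >= lo) & (obs["year"] <= hi)]
        per_year = []
        for _, row in obs.iterrows():
            if f.kind == FactorKind.quantitative:
                v = row["value"]
                fs = score_factor(
                    f, site_id, value=None if pd.isna(v) else float(v)
                )
            else:
                st = row["state"]
                fs = score_factor(f, site_id, state=None if pd.isna(st) else st)
            if fs.score is not None:
                per_year.append(fs.score)
        if not per_year:
            out.append(FactorScore(f.factor_id, service_id, site_id, None, "missing"))
        else:
            basis = f.kind.value
            out.append(FactorScore(
                f.factor_id, service_id, site_id,
                sum(per_year) / len(per_year), basis,
            ))
    return out


def run_assessment(
    cfg: ValidatedConfig,
    indicators: pd.DataFrame,
    factors: Optional[pd.DataFrame] = None,
) -> AssessmentResult:
    """Score every declared (site, service) cell of the assessment.

    Parameters
    ----------
    cfg
        A validated configuration.
    indicators
        Tidy indicator records: ``site_id, service_id, year, value``.
    factors
        Tidy factor states: ``site_id, service_id, factor_id, year, value,
        state`` (optional; without it every PR defaults to 0).
    """
    if factors is None:
        factors = pd.DataFrame(
            columns=["site_id", "service_id", "factor_id", "year", "value", "state"]
        )
    _check_ids(cfg, indicators, factors)
    ass = cfg.assessment
    lo_year, hi_year = ass.window

    result = AssessmentResult(config=cfg, reference_points={}, screenings={})
    for svc in cfg.services:
        sid = svc.service_id
        panel = indicators[
            (indicators["service_id"] == sid)
            & (indicators["year"] >= lo_year)
            & (indicators["year"] <= hi_year)
        ][["site_id", "year", "value"]]

        screening = screen_outliers(panel, ass.outlier_k)
        ref = reference_point(
            screening.retained, sid, ass.window,
            override=ass.reference_overrides.get(sid),
        )
        result.screenings[sid] = screening
        result.reference_points[sid] = ref

        for site in cfg.sites:
            site_id = site.site_id
            cell_flags = list(screening.flags)
            if ref.override:
                cell_flags.append(F.REFERENCE_OVERRIDE)

            row = panel[(panel["site_id"] == site_id)
                        & (panel["year"] == ass.evaluation_year)]
            X_eval = float(row["value"].iloc[0]) if len(row) else None
            excluded_site = screening.excluded[
                screening.excluded["site_id"] == site_id
            ]
            if X_eval is not None and (
                excluded_site["year"] == ass.evaluation_year
            ).any():
                cell_flags.append(F.OUTLIER_EVAL_YEAR)

            x, x_flags = present_status(X_eval, ref)
            cell_flags += [f for f in x_flags if f not in cell_flags]

            retained_site = screening.retained[
                screening.retained["site_id"] == site_id
            ].copy()
            retained_site["x"] = retained_site["value"] / ref.X_R
            tr = fit_trend(
                retained_site.rename(columns={"value": "X"}),
                ass.min_trend_points,
            )
            cell_flags += [f for f in tr.flags if f not in cell_flags]

            fscores = _factor_scores_for(cfg, factors, site_id, sid)
            pr, pr_flags = aggregate_pr(fscores)
            cell_flags += [f for f in pr_flags if f not in cell_flags]

            scores = score_service(
                site_id, sid,
                x=x if x is not None else math.nan,
                trend_T=tr.T,
                pr=pr,
                beta=ass.beta,
                report_scale=ass.report_scale,
                trend_ci=(tr.T_lower, tr.T_upper),
                extra_flags=cell_flags,
            )
            result.cells[(site_id, sid)] = CellResult(
                site_id=site_id,
                service_id=sid,
                ref=ref,
                X_eval=X_eval,
                trend=tr,
                factor_scores=fscores,
                scores=scores,
                retained=retained_site.reset_index(drop=True),
                excluded=excluded_site.reset_index(drop=True),
            )
    return result
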
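"""Synthetic multi-site assessment panels with known ground truth.

Every stage of the pipeline is testable without field data: a scenario
declares, per service and site, a base indicator level and a true linear
drift, plus observation noise and an outlier-injection rate, and per factor
a state schedule. The generator emits exactly the delimited files the
ingestion layer reads, alongside a ground-truth record (true slopes, true
factor scores, true PR, true sustainability) for parameter-recovery tests.

The default scenario, :func:`tokyo_bay_like`, mimics the shape of the study
system the method was designed around: four tidal flats in one enclosed bay
(two artificial, two natural) observed over a five-year window, with a
food-provision-style service driven by eight environmental factors, a
filtration-style service, a diversity service, and a research service with
no evaluated conceptual model.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .config import ValidatedConfig, validate_config
from .pr import score_factor

#: Multiplicative shock applied to an injected outlier observation.
OUTLIER_SHOCK = 8.0


class ServiceScenario(BaseModel):
    """True data-generating process of one service's indicator per site."""

    model_config = ConfigDict(frozen=True)

    base_level: dict[str, float]  # site_id -> X at the first window year
    slope: dict[str, float] = Field(default_factory=dict)  # site_id -> per-year drift
    noise_sd: float = Field(default=0.0, ge=0.0)
    outlier_rate: float = Field(default=0.0, ge=0.0, le=1.0)


class ScenarioSpec(BaseModel):
    """A complete synthetic assessment: config + generating processes."""

    model_config = ConfigDict(frozen=True)

    seed: int = Field(ge=0, lt=2**31)
    config: dict  # raw assessment config document (validated on generation)
    services_sim: dict[str, ServiceScenario]
    #: service_id -> factor_id -> site_id -> {year: value-or-state}
    factor_schedule: dict[str, dict[str, dict[str, dict[int, float | str]]]] = Field(
        default_factory=dict
    )


@dataclass
class SyntheticPanel:
    config: ValidatedConfig
    raw_config: dict
    indicators: pd.DataFrame  # site_id, service_id, year, value
    factors: pd.DataFrame     # site_id, service_id, factor_id, year, value, state
    ground_truth: dict


def simulate_status_series(
    rng: np.random.Generator,
    base: float,
    slope: float,
    sd: float,
    years: list[int],
    outlier_rate: float = 0.0,
) -> list[float]:
    """One indicator time series: linear drift + truncated Gaussian noise.

    Values are truncated at zero (indicators are non-negative quantities);
    outliers are injected as multiplicative shocks at the stated rate.
    """
    first = years[0]
    out = []
    for y in years:
        v = base + slope * (y - first)
        if sd > 0:
            v += rng.normal(0.0, sd)
        v = max(0.0, v)
        if outlier_rate > 0 and rng.uniform() < outlier_rate:
            v *= OUTLIER_SHOCK
        out.append(v)
    return out


def generate_panel(spec: ScenarioSpec) -> SyntheticPanel:
    """Generate the full input panel plus its ground-truth record.

    The same seed yields byte-identical files from :func:`write_panel`;
    draws are consumed in the fixed (service, site, year) iteration order
    of the validated config.
    """
    cfg = validate_config(spec.config)
    ass = cfg.assessment
    years = list(range(ass.first_year, ass.evaluation_year + 1))
    rng = np.random.default_rng(spec.seed)

    ind_rows = []
    truth_services: dict[str, dict] = {}
    for svc in cfg.services:
        sim = spec.services_sim.get(svc.service_id)
        if sim is None:
            continue
        # noiseless panel for the true reference point
        clean: dict[str, list[float]] = {}
        for site in cfg.sites:
            if site.site_id not in sim.base_level:
                continue
            b = sim.base_level[site.site_id]
            sl = sim.slope.get(site.site_id, 0.0)
            clean[site.site_id] = [
                max(0.0, b + sl * (y - years[0])) for y in years
            ]
        x_r_true = max((max(v) for v in clean.values()), default=0.0)

        per_site_truth = {}
        for site in cfg.sites:
            if site.site_id not in clean:
                continue
            b = sim.base_level[site.site_id]
            sl = sim.slope.get(site.site_id, 0.0)
            series = simulate_status_series(
                rng, b, sl, sim.noise_sd, years, sim.outlier_rate
            )
            for y, v in zip(years, series):
                ind_rows.append(
                    {"site_id": site.site_id, "service_id": svc.service_id,
                     "year": y, "value": v}
                )
            truth = {"base_level": b, "slope_raw": sl}
            if x_r_true > 0:
                truth["x_eval_true"] = clean[site.site_id][-1] / x_r_true
                truth["T_true"] = max(-1.0, min(1.0, 5.0 * sl / x_r_true))
            per_site_truth[site.site_id] = truth
        truth_services[svc.service_id] = {
            "X_R_true": x_r_true,
            "noise_sd": sim.noise_sd,
            "outlier_rate": sim.outlier_rate,
            "sites": per_site_truth,
        }

    fac_rows = []
    truth_pr: dict[str, dict] = {}
    for svc in cfg.services:
        sched = spec.factor_schedule.get(svc.service_id, {})
        fdefs = cfg.conceptual_model.for_service(svc.service_id)
        for site in cfg.sites:
            fscores = []
            for f in fdefs:
                per_site = sched.get(f.factor_id, {}).get(site.site_id, {})
                for y, obs in sorted(per_site.items()):
                    row = {"site_id": site.site_id, "service_id": svc.service_id,
                           "factor_id": f.factor_id, "year": int(y),
                           "value": "", "state": ""}
                    if f.kind.value == "quantitative":
                        row["value"] = float(obs)
                    else:
                        row["state"] = str(obs)
                    fac_rows.append(row)
                eval_obs = per_site.get(ass.evaluation_year)
                if f.kind.value == "quantitative":
                    fscores.append(score_factor(
                        f, site.site_id,
                        value=None if eval_obs is None else float(eval_obs)))
                else:
                    fscores.append(score_factor(f, site.site_id, state=eval_obs))
            scored = [s.score for s in fscores if s.score is not None]
            pr_true = sum(scored) / len(scored) if scored else None
            truth_pr.setdefault(svc.service_id, {})[site.site_id] = {
                "PR_true": pr_true,
                "factor_scores": {
                    s.factor_id: s.score for s in fscores
                },
            }

    # sustainability truth: beta*T + (1-beta)*PR with PR defaulting to 0
    beta = ass.beta
    for sid, svc_truth in truth_services.items():
        for site_id, t in svc_truth["sites"].items():
            if "T_true" not in t:
                continue
            pr = truth_pr.get(sid, {}).get(site_id, {}).get("PR_true")
            pr_eff = 0.0 if pr is None else pr
            t["S_true"] = beta * t["T_true"] + (1.0 - beta) * pr_eff

    indicators = pd.DataFrame(
        ind_rows, columns=["site_id", "service_id", "year", "value"]
    )
    factors = pd.DataFrame(
        fac_rows,
        columns=["site_id", "service_id", "factor_id", "year", "value", "state"],
    )
    ground_truth = {
        "seed": spec.seed,
        "beta": beta,
        "services": truth_services,
        "pr": truth_pr,
    }
    return SyntheticPanel(
        config=cfg, raw_config=spec.config, indicators=indicators,
        factors=factors, ground_truth=ground_truth,
    )


def write_panel(panel: SyntheticPanel, outdir) -> dict[str, Path]:
    """Write the panel as the exact file formats the ingestion layer reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "config": out / "config.yaml",
        "indicators": out / "indicators.csv",
        "factors": out / "factors.csv",
        "ground_truth": out / "ground_truth.json",
    }
    with open(paths["config"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(panel.raw_config, fh, sort_keys=True)
    panel.indicators.to_csv(
        paths["indicators"], index=False, float_format="%.12g", lineterminator="\n"
    )
    panel.factors.to_csv(
        paths["factors"], index=False, float_format="%.12g", lineterminator="\n"
    )
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(panel.ground_truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def _years(first: int, last: int) -> list[int]:
    return list(range(first, last + 1))


def tokyo_bay_like(seed: int = 0, noise_sd_scale: float = 1.0) -> ScenarioSpec:
    """Default demo scenario: four flats in one enclosed bay, 2009-2013.

    Two artificial sites (a small terrace-type flat ``A1`` and a large,
    long-established public flat ``A2``) and two natural river-mouth flats
    (``N1``, ``N2``). Indicator levels, drifts and noise are chosen to span
    the behaviours the method must handle: improving and declining services,
    a PR-less research service, and qualitative factor mixes that make some
    cells unsustainable.
    """
    first, evaluation = 2009, 2013
    yrs = _years(first, evaluation)
    config = {
        "assessment": {
            "evaluation_year": evaluation,
            "window_years": 5,
        },
        "sites": [
            {"site_id": "A1", "name": "artificial terrace flat",
             "natural_or_artificial": "artificial", "area_m2": 450.0,
             "coastline_m": 35.0},
            {"site_id": "A2", "name": "artificial beach flat",
             "natural_or_artificial": "artificial", "area_m2": 150000.0,
             "coastline_m": 800.0},
            {"site_id": "N1", "name": "river-mouth flat north",
             "natural_or_artificial": "natural", "area_m2": 250000.0,
             "coastline_m": 2500.0},
            {"site_id": "N2", "name": "river-mouth flat south",
             "natural_or_artificial": "natural", "area_m2": 6500000.0,
             "coastline_m": 3500.0},
        ],
        "services": [
            {"service_id": "food_provision", "name": "Food provision",
             "index_description": "wet weight of commercially important species",
             "spatial_basis": "per_unit_area", "temporal_statistic": "annual_mean",
             "unit": "g/m^2"},
            {"service_id": "suspended_removal", "name": "Suspended material removal",
             "index_description": "bivalve water filtration volume",
             "spatial_basis": "per_unit_area", "temporal_statistic": "annual_mean",
             "unit": "g/m^2/day"},
            {"service_id": "research", "name": "Research",
             "index_description": "number of papers and reports",
             "spatial_basis": "whole_site", "temporal_statistic": "annual_total",
             "unit": "papers/area/year"},
            {"service_id": "degree_of_diversity", "name": "Degree of diversity",
             "index_description": "Shannon-Wiener diversity index",
             "spatial_basis": "whole_site", "temporal_statistic": "annual_mean",
             "unit": ""},
        ],
        "factors": [
            # food provision: the eight-factor conceptual model
            {"factor_id": "anoxic_water", "service_id": "food_provision",
             "kind": "quantitative", "lo_threshold": 2.0, "hi_threshold": 6.0,
             "description": "dissolved oxygen, mg/L"},
            {"factor_id": "primary_productivity", "service_id": "food_provision",
             "kind": "quantitative", "lo_threshold": 1.0, "hi_threshold": 5.0,
             "description": "chlorophyll-a, ug/L"},
            {"factor_id": "blue_tide", "service_id": "food_provision",
             "kind": "qualitative", "description": "blue-tide occurrence"},
            {"factor_id": "predatory_species", "service_id": "food_provision",
             "kind": "qualitative",
             "description": "predators/competitors of commercial species"},
            {"factor_id": "stability_of_ground", "service_id": "food_provision",
             "kind": "qualitative", "description": "ground stability"},
            {"factor_id": "source_of_juveniles", "service_id": "food_provision",
             "kind": "qualitative", "description": "nearby source tidal flat"},
            {"factor_id": "management_of_ground", "service_id": "food_provision",
             "kind": "qualitative", "description": "ground-condition management"},
            {"factor_id": "protection_of_species", "service_id": "food_provision",
             "kind": "qualitative", "description": "species-protection efforts"},
            # suspended material removal
            {"factor_id": "anoxic_water", "service_id": "suspended_removal",
             "kind": "quantitative", "lo_threshold": 2.0, "hi_threshold": 6.0,
             "description": "dissolved oxygen, mg/L"},
            {"factor_id": "blue_tide", "service_id": "suspended_removal",
             "kind": "qualitative", "description": "blue-tide occurrence"},
            {"factor_id": "stability_of_ground", "service_id": "suspended_removal",
             "kind": "qualitative", "description": "ground stability"},
            # degree of diversity
            {"factor_id": "alien_species", "service_id": "degree_of_diversity",
             "kind": "qualitative", "description": "alien-species pressure"},
            {"factor_id": "protection_of_species", "service_id": "degree_of_diversity",
             "kind": "qualitative", "description": "species-protection efforts"},
            # research deliberately has no conceptual model (PR not evaluated)
        ],
    }

    services_sim = {
        # g/m^2 wet weight: the young artificial flat is productive but
        # declining; the natural flats are lower but stable or improving.
        # Cross-site contrasts are kept inside the pooled 2-sigma band so
        # that screening targets injected shocks, not genuine site levels.
        "food_provision": ServiceScenario(
            base_level={"A1": 18.0, "A2": 11.0, "N1": 8.0, "N2": 12.0},
            slope={"A1": -1.2, "A2": 0.4, "N1": 0.1, "N2": 0.6},
            noise_sd=1.0 * noise_sd_scale,
            outlier_rate=0.02,
        ),
        "suspended_removal": ServiceScenario(
            base_level={"A1": 60.0, "A2": 30.0, "N1": 22.0, "N2": 13.0},
            slope={"A1": 3.0, "A2": 1.5, "N1": 0.8, "N2": 0.5},
            noise_sd=3.0 * noise_sd_scale,
            outlier_rate=0.02,
        ),
        "research": ServiceScenario(
            base_level={"A1": 6.0, "A2": 1.0, "N1": 7.0, "N2": 6.0},
            slope={"A1": 0.5, "A2": 0.0, "N1": 0.8, "N2": 0.9},
            noise_sd=0.8 * noise_sd_scale,
        ),
        "degree_of_diversity": ServiceScenario(
            base_level={"A1": 2.1, "A2": 2.35, "N1": 2.3, "N2": 2.0},
            slope={"A1": 0.05, "A2": 0.04, "N1": -0.01, "N2": 0.01},
            noise_sd=0.08 * noise_sd_scale,
        ),
    }

    def qual(states: dict[str, str]) -> dict[str, dict[int, str]]:
        return {site: {evaluation: st} for site, st in states.items()}

    do_traj = {
        # mg/L at the evaluation year plus history (anoxia at the enclosed
        # port site A1, healthy elsewhere)
        "A1": {y: v for y, v in zip(yrs, [4.0, 3.6, 3.4, 3.2, 3.0])},
        "A2": {y: v for y, v in zip(yrs, [5.6, 5.8, 6.1, 6.0, 6.2])},
        "N1": {y: v for y, v in zip(yrs, [5.0, 5.2, 5.1, 5.3, 5.4])},
        "N2": {y: v for y, v in zip(yrs, [4.4, 4.6, 4.2, 4.5, 4.3])},
    }
    chla_traj = {
        "A1": {evaluation: 4.2}, "A2": {evaluation: 3.6},
        "N1": {evaluation: 2.6}, "N2": {evaluation: 3.2},
    }

    factor_schedule = {
        "food_provision": {
            "anoxic_water": do_traj,
            "primary_productivity": chla_traj,
            "blue_tide": qual({"A1": "negative", "A2": "positive",
                               "N1": "positive", "N2": "negative"}),
            "predatory_species": qual({"A1": "negative", "A2": "positive",
                                       "N1": "negative", "N2": "positive"}),
            "stability_of_ground": qual({"A1": "negative", "A2": "positive",
                                         "N1": "positive", "N2": "positive"}),
            "source_of_juveniles": qual({"A1": "positive", "A2": "positive",
                                         "N1": "positive", "N2": "positive"}),
            "management_of_ground": qual({"A1": "positive", "A2": "negative",
                                          "N1": "negative", "N2": "unknown"}),
            "protection_of_species": qual({"A1": "negative", "A2": "negative",
                                           "N1": "positive", "N2": "positive"}),
        },
        "suspended_removal": {
            "anoxic_water": do_traj,
            "blue_tide": qual({"A1": "negative", "A2": "positive",
                               "N1": "positive", "N2": "negative"}),
            "stability_of_ground": qual({"A1": "negative", "A2": "positive",
                                         "N1": "positive", "N2": "positive"}),
        },
        "degree_of_diversity": {
            "alien_species": qual({"A1": "negative", "A2": "negative",
                                   "N1": "negative", "N2": "positive"}),
            "protection_of_species": qual({"A1": "negative", "A2": "positive",
                                           "N1": "positive", "N2": "positive"}),
        },
    }

    return ScenarioSpec(
        seed=seed,
        config=config,
        services_sim=services_sim,
        factor_schedule=factor_schedule,
    )
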
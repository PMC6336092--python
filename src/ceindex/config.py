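"""Assessment configuration: domain types, schema validation, serialization.

A single YAML/JSON document declares everything that is *chosen* rather than
*measured*: the sites under comparison, the services and their aggregation
conventions, the conceptual model (which environmental factors act on which
service, and how each is scored), and the global assessment parameters
(evaluation year, window, the trend-vs-PR weight beta, the outlier rule).

Top-level keys: ``assessment``, ``sites``, ``services``, ``factors``.
"""
from __future__ import annotations

import enum
import json
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import SchemaError

#: Default weight of the measured trend vs the pressure-resilience score in
#: the near-term projection: trend counts 2:1 over PR.
DEFAULT_BETA = 0.67

#: Default multiplier k of the outlier rule |X - mean| > k * sd.
DEFAULT_OUTLIER_K = 2.0

#: Default assessment window: the evaluation year plus the four preceding years.
DEFAULT_WINDOW_YEARS = 5


class ReportScale(str, enum.Enum):
    unit = "unit"
    percent100 = "percent100"


class SpatialBasis(str, enum.Enum):
    per_unit_area = "per_unit_area"
    whole_site = "whole_site"


class TemporalStatistic(str, enum.Enum):
    annual_mean = "annual_mean"
    annual_total = "annual_total"
    annual_max = "annual_max"
    annual_min = "annual_min"


class FactorKind(str, enum.Enum):
    quantitative = "quantitative"
    qualitative = "qualitative"


class Direction(str, enum.Enum):
    increasing_good = "increasing_good"
    decreasing_good = "decreasing_good"


class FactorYears(str, enum.Enum):
    """Which factor observations feed the PR score."""

    evaluation_year = "evaluation_year"
    window_mean = "window_mean"


class SiteKind(str, enum.Enum):
    natural = "natural"
    artificial = "artificial"


class AssessmentConfig(BaseModel):
    """Global parameters of one assessment run."""

    model_config = ConfigDict(frozen=True)

    evaluation_year: int
    window_years: int = Field(default=DEFAULT_WINDOW_YEARS, ge=2)
    beta: float = Field(default=DEFAULT_BETA, ge=0.0, le=1.0)
    outlier_k: float = Field(default=DEFAULT_OUTLIER_K, gt=0.0)
    report_scale: ReportScale = ReportScale.percent100
    min_trend_points: int = Field(default=3, ge=1)
    factor_years: FactorYears = FactorYears.evaluation_year
    #: Optional fixed reference points per service (e.g. a pre-degradation
    #: ideal for waters where the recent maximum is itself degraded).
    reference_overrides: dict[str, float] = Field(default_factory=dict)

    @property
    def first_year(self) -> int:
        return self.evaluation_year - self.window_years + 1

    @property
    def window(self) -> tuple[int, int]:
        return (self.first_year, self.evaluation_year)

    @model_validator(mode="after")
    def _positive_overrides(self) -> "AssessmentConfig":
        for sid, xr in self.reference_overrides.items():
            if not xr > 0:
                raise ValueError(f"reference override for {sid!r} must be positive")
        return self


class Site(BaseModel):
    model_config = ConfigDict(frozen=True)

    site_id: str
    name: str = ""
    natural_or_artificial: SiteKind = SiteKind.natural
    area_m2: Optional[float] = Field(default=None, gt=0)
    coastline_m: Optional[float] = Field(default=None, gt=0)


class ServiceDef(BaseModel):
    """One service or sub-service and its indicator conventions."""

    model_config = ConfigDict(frozen=True)

    service_id: str
    name: str = ""
    index_description: str = ""
    spatial_basis: SpatialBasis = SpatialBasis.per_unit_area
    temporal_statistic: TemporalStatistic = TemporalStatistic.annual_mean
    unit: str = ""


class FactorDefinition(BaseModel):
    """Scoring model of one environmental factor acting on one service.

    Quantitative factors carry two anchors: the score is -1 at or below
    ``lo_threshold``, +1 at or above ``hi_threshold`` and linear in between
    (for ``increasing_good``; the ``decreasing_good`` line is the mirror
    image). Qualitative factors score +/- ``qualitative_magnitude`` on the
    observed presence of their resilience/pressure condition.
    """

    model_config = ConfigDict(frozen=True)

    factor_id: str
    service_id: str
    kind: FactorKind
    lo_threshold: Optional[float] = None
    hi_threshold: Optional[float] = None
    direction: Direction = Direction.increasing_good
    qualitative_magnitude: float = Field(default=0.5, gt=0.0, le=1.0)
    weight: float = Field(default=1.0, gt=0.0)
    description: str = ""

    @model_validator(mode="after")
    def _thresholds_match_kind(self) -> "FactorDefinition":
        if self.kind is FactorKind.quantitative:
            if self.lo_threshold is None or self.hi_threshold is None:
                raise ValueError(
                    f"quantitative factor {self.factor_id!r} requires both "
                    "lo_threshold and hi_threshold"
                )
            if not self.lo_threshold < self.hi_threshold:
                raise ValueError(
                    f"factor {self.factor_id!r}: lo_threshold must be strictly "
                    "below hi_threshold (use direction=decreasing_good to flip "
                    "the orientation)"
                )
        else:
            if self.lo_threshold is not None or self.hi_threshold is not None:
                raise ValueError(
                    f"qualitative factor {self.factor_id!r} must not carry thresholds"
                )
        return self


class ConceptualModel(BaseModel):
    """The declared mapping service -> environmental factors."""

    model_config = ConfigDict(frozen=True)

    factors: tuple[FactorDefinition, ...]

    def for_service(self, service_id: str) -> list[FactorDefinition]:
        return [f for f in self.factors if f.service_id == service_id]

    def get(self, service_id: str, factor_id: str) -> FactorDefinition:
        for f in self.factors:
            if f.service_id == service_id and f.factor_id == factor_id:
                return f
        raise KeyError((service_id, factor_id))


class ValidatedConfig(BaseModel):
    """The fully cross-referenced result of :func:`validate_config`."""

    model_config = ConfigDict(frozen=True)

    assessment: AssessmentConfig
    sites: tuple[Site, ...]
    services: tuple[ServiceDef, ...]
    conceptual_model: ConceptualModel

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    @property
    def service_ids(self) -> list[str]:
        return [s.service_id for s in self.services]

    def service(self, service_id: str) -> ServiceDef:
        for s in self.services:
            if s.service_id == service_id:
                return s
        raise KeyError(service_id)


def _as_mapping(raw) -> dict:
    if isinstance(raw, dict):
        return raw
    raise SchemaError(f"config root must be a mapping, got {type(raw).__name__}")


def validate_config(raw: dict | str) -> ValidatedConfig:
    """Validate a raw config document into cross-referenced domain objects.

    Parameters
    ----------
    raw
        Either an already-parsed mapping or YAML/JSON text with top-level
        keys ``assessment``, ``sites``, ``services``, ``factors``.

    Raises
    ------
    SchemaError
        On any schema violation, naming the offending id where applicable.
    """
    if isinstance(raw, str):
        raw = yaml.safe_load(raw)
    doc = _as_mapping(raw)

    try:
        assessment = AssessmentConfig(**_as_mapping(doc.get("assessment", {})))
        sites = tuple(Site(**s) for s in doc.get("sites", []))
        services = tuple(ServiceDef(**s) for s in doc.get("services", []))
        factors = tuple(FactorDefinition(**f) for f in doc.get("factors", []))
    except SchemaError:
        raise
    except Exception as exc:  # pydantic ValidationError, TypeError on bad shapes
        raise SchemaError(str(exc)) from exc

    site_ids = [s.site_id for s in sites]
    if len(set(site_ids)) != len(site_ids):
        dup = sorted({i for i in site_ids if site_ids.count(i) > 1})
        raise SchemaError(f"duplicate site_id(s): {dup}")
    service_ids = [s.service_id for s in services]
    if len(set(service_ids)) != len(service_ids):
        dup = sorted({i for i in service_ids if service_ids.count(i) > 1})
        raise SchemaError(f"duplicate service_id(s): {dup}")
    if not sites:
        raise SchemaError("at least one site must be declared")
    if not services:
        raise SchemaError("at least one service must be declared")

    declared = set(service_ids)
    for f in factors:
        if f.service_id not in declared:
            raise SchemaError(
                f"factor {f.factor_id!r} references undeclared service {f.service_id!r}"
            )
    seen: set[tuple[str, str]] = set()
    for f in factors:
        key = (f.service_id, f.factor_id)
        if key in seen:
            raise SchemaError(
                f"duplicate factor {f.factor_id!r} for service {f.service_id!r}"
            )
        seen.add(key)
    for sid in assessment.reference_overrides:
        if sid not in declared:
            raise SchemaError(
                f"reference override names undeclared service {sid!r}"
            )

    return ValidatedConfig(
        assessment=assessment,
        sites=sites,
        services=services,
        conceptual_model=ConceptualModel(factors=factors),
    )


def serialize_config(cfg: ValidatedConfig) -> dict:
    """Normalized plain-dict form of a validated config (round-trips)."""
    return {
        "assessment": cfg.assessment.model_dump(mode="json"),
        "sites": [s.model_dump(mode="json") for s in cfg.sites],
        "services": [s.model_dump(mode="json") for s in cfg.services],
        "factors": [f.model_dump(mode="json") for f in cfg.conceptual_model.factors],
    }


def config_json_schema() -> dict:
    """JSON schema of the config document (for editor tooling / docs)."""
    return {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "title": "CEI assessment configuration",
        "type": "object",
        "required": ["assessment", "sites", "services"],
        "properties": {
            "assessment": AssessmentConfig.model_json_schema(),
            "sites": {"type": "array", "items": Site.model_json_schema()},
            "services": {"type": "array", "items": ServiceDef.model_json_schema()},
            "factors": {
                "type": "array",
                "items": FactorDefinition.model_json_schema(),
            },
        },
    }


def load_config(path) -> ValidatedConfig:
    """Read and validate a YAML/JSON config file."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if str(path).endswith(".json"):
        return validate_config(json.loads(text))
    return validate_config(text)
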
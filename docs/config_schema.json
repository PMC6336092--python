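{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "CEI assessment configuration",
 "type": "object",
 "required": [
  "assessment",
  "sites",
  "services"
 ],
 "properties": {
  "assessment": {
   "$defs": {
    "FactorYears": {
     "description": "Which factor observations feed the PR score.",
     "enum": [
      "evaluation_year",
      "window_mean"
     ],
     "title": "FactorYears",
     "type": "string"
    },
    "ReportScale": {
     "enum": [
      "unit",
      "percent100"
     ],
     "title": "ReportScale",
     "type": "string"
    }
   },
   "description": "Global parameters of one assessment run.",
   "properties": {
    "evaluation_year": {
     "title": "Evaluation Year",
     "type": "integer"
    },
    "window_years": {
     "default": 5,
     "minimum": 2,
     "title": "Window Years",
     "type": "integer"
    },
    "beta": {
     "default": 0.67,
     "maximum": 1.0,
     "minimum": 0.0,
     "title": "Beta",
     "type": "number"
    },
    "outlier_k": {
     "default": 2.0,
     "exclusiveMinimum": 0.0,
     "title": "Outlier K",
     "type": "number"
    },
    "report_scale": {
     "$ref": "#/$defs/ReportScale",
     "default": "percent100"
    },
    "min_trend_points": {
     "default": 3,
     "minimum": 1,
     "title": "Min Trend Points",
     "type": "integer"
    },
    "factor_years": {
     "$ref": "#/$defs/FactorYears",
     "default": "evaluation_year"
    },
    "reference_overrides": {
     "additionalProperties": {
      "type": "number"
     },
     "title": "Reference Overrides",
     "type": "object"
    }
   },
   "required": [
    "evaluation_year"
   ],
   "title": "AssessmentConfig",
   "type": "object"
  },
  "sites": {
   "type": "array",
   "items": {
    "$defs": {
     "SiteKind": {
      "enum": [
       "natural",
       "artificial"
      ],
      "title": "SiteKind",
      "type": "string"
     }
    },
    "properties": {
     "site_id": {
      "title": "Site Id",
      "type": "string"
     },
     "name": {
      "default": "",
      "title": "Name",
      "type": "string"
     },
     "natural_or_artificial": {
      "$ref": "#/$defs/SiteKind",
      "default": "natural"
     },
     "area_m2": {
      "anyOf": [
       {
        "exclusiveMinimum": 0,
        "type": "number"
       },
       {
        "type": "null"
       }
      ],
      "default": null,
      "title": "Area M2"
     },
     "coastline_m": {
      "anyOf": [
       {
        "exclusiveMinimum": 0,
        "type": "number"
       },
       {
        "type": "null"
       }
      ],
      "default": null,
      "title": "Coastline M"
     }
    },
    "required": [
     "site_id"
    ],
    "title": "Site",
    "type": "object"
   }
  },
  "services": {
   "type": "array",
   "items": {
    "$defs": {
     "SpatialBasis": {
      "enum": [
       "per_unit_area",
       "whole_site"
      ],
      "title": "SpatialBasis",
      "type": "string"
     },
     "TemporalStatistic": {
      "enum": [
       "annual_mean",
       "annual_total",
       "annual_max",
       "annual_min"
      ],
      "title": "TemporalStatistic",
      "type": "string"
     }
    },
    "description": "One service or sub-service and its indicator conventions.",
    "properties": {
     "service_id": {
      "title": "Service Id",
      "type": "string"
     },
     "name": {
      "default": "",
      "title": "Name",
      "type": "string"
     },
     "index_description": {
      "default": "",
      "title": "Index Description",
      "type": "string"
     },
     "spatial_basis": {
      "$ref": "#/$defs/SpatialBasis",
      "default": "per_unit_area"
     },
     "temporal_statistic": {
      "$ref": "#/$defs/TemporalStatistic",
      "default": "annual_mean"
     },
     "unit": {
      "default": "",
      "title": "Unit",
      "type": "string"
     }
    },
    "required": [
     "service_id"
    ],
    "title": "ServiceDef",
    "type": "object"
   }
  },
  "factors": {
   "type": "array",
   "items": {
    "$defs": {
     "Direction": {
      "enum": [
       "increasing_good",
       "decreasing_good"
      ],
      "title": "Direction",
      "type": "string"
     },
     "FactorKind": {
      "enum": [
       "quantitative",
       "qualitative"
      ],
      "title": "FactorKind",
      "type": "string"
     }
    },
    "description": "Scoring model of one environmental factor acting on one service.\n\nQuantitative factors carry two anchors: the score is -1 at or below\n``lo_threshold``, +1 at or above ``hi_threshold`` and linear in between\n(for ``increasing_good``; the ``decreasing_good`` line is the mirror\nimage). Qualitative factors score +/- ``qualitative_magnitude`` on the\nobserved presence of their resilience/pressure condition.",
    "properties": {
     "factor_id": {
      "title": "Factor Id",
      "type": "string"
     },
     "service_id": {
      "title": "Service Id",
      "type": "string"
     },
     "kind": {
      "$ref": "#/$defs/FactorKind"
     },
     "lo_threshold": {
      "anyOf": [
       {
        "type": "number"
       },
       {
        "type": "null"
       }
      ],
      "default": null,
      "title": "Lo Threshold"
     },
     "hi_threshold": {
      "anyOf": [
       {
        "type": "number"
       },
       {
        "type": "null"
       }
      ],
      "default": null,
      "title": "Hi Threshold"
     },
     "direction": {
      "$ref": "#/$defs/Direction",
      "default": "increasing_good"
     },
     "qualitative_magnitude": {
      "default": 0.5,
      "exclusiveMinimum": 0.0,
      "maximum": 1.0,
      "title": "Qualitative Magnitude",
      "type": "number"
     },
     "weight": {
      "default": 1.0,
      "exclusiveMinimum": 0.0,
      "title": "Weight",
      "type": "number"
     },
     "description": {
      "default": "",
      "title": "Description",
      "type": "string"
     }
    },
    "required": [
     "factor_id",
     "service_id",
     "kind"
    ],
    "title": "FactorDefinition",
    "type": "object"
   }
  }
 }
}
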
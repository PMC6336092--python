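"""Condition codes attached to score cells and intermediate results.

Flags are plain strings so they serialize directly into CSV/JSON reports;
this module is the single registry so typos fail loudly in tests.
"""

NO_SCREENING = "NO_SCREENING"          # fewer than 2 pooled values; outlier rule not applied
NO_DATA = "NO_DATA"                    # evaluation-year indicator value missing
OUTLIER_EVAL_YEAR = "OUTLIER_EVAL_YEAR"  # evaluation-year value screened out but still normalized
NO_TREND_DATA = "NO_TREND_DATA"        # too few in-window points; trend set to 0
TREND_CLAMPED = "TREND_CLAMPED"        # |5t| exceeded 1 and was clamped
CI_CLAMPED = "CI_CLAMPED"              # a trend CI bound was clamped to [-1, 1]
FACTOR_UNKNOWN = "FACTOR_UNKNOWN"      # qualitative state unknown; factor excluded from PR
NO_PR = "NO_PR"                        # no factor could be scored for the (site, service)
PR_DEFAULTED = "PR_DEFAULTED"          # PR unavailable; 0 used in the future-status projection
CLAMPED_FUTURE = "CLAMPED_FUTURE"      # projected future status exceeded 1 and was clamped
X_ZERO = "X_ZERO"                      # present status 0; sustainability undefined
REFERENCE_OVERRIDE = "REFERENCE_OVERRIDE"  # user-supplied reference point in effect

ALL_FLAGS = frozenset(
    v for k, v in vars().items() if k.isupper() and isinstance(v, str)
)
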
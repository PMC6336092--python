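# Methods

## The index

`ceindex` scores coastal ecosystem services — the benefits a tidal flat or
similar habitat provides (food provision, coastal protection, water-front
use, sense of place, water-quality regulation, biodiversity) — for a set of
sites compared within one water body. The design follows the
reference-point-and-sustainability logic of Ocean-Health-Index-style
composite indicators, specialized to small restoration or construction
projects where artificial habitats are judged against nearby natural ones.

For each service *i* at each site, four quantities combine into the reported
scores:

- **Present status** `x_i = X_i / X_R`, the evaluation-year indicator value
  normalized by the reference point `X_R`: the maximum retained indicator
  value over *all* compared sites across the assessment window (default the
  most recent 5 years). Using the cross-site window maximum makes the score
  a relative comparison among the sites rather than a distance to an
  absolute target; a fixed user-supplied `X_R` can be configured per service
  for waters where the recent maximum is itself degraded.
- **Trend** `T_i = 5 t_i`, five times the OLS slope `t_i` of the normalized
  status over the window, clamped to [−1, +1]. With no usable history the
  trend is 0 (flag `NO_TREND_DATA`).
- **Pressure–resilience** `PR_i`, the unweighted mean of per-factor scores
  `PR_{i,j} ∈ [−1, +1]` from the service's conceptual model (below).
- **Near-term future status**
  `x_{i,F} = (1 + β T_i + (1 − β) PR_i) · x_i` with β = 0.67 by default,
  weighting the directly measured trend 2:1 over the indirectly inferred
  PR score.

The reported **service score** is `I_i = (x_i + x_{i,F}) / 2`, printed on a
0–100 scale, and the **sustainability score** is
`S_i = (x_{i,F} − x_i) / x_i`, printed as a signed percent. Where no
clamping occurs, `S_i = β T_i + (1 − β) PR_i` exactly — the pipeline asserts
this identity at 1e−9 on every cell it scores.

## Outlier screening

Indicator values more than `k` sample standard deviations (default `k` = 2,
ddof = 1) from the mean are excluded before reference-point selection and
trend fitting. The sample is the pooled per-service panel — all sites ×
all window years — screened in a single pass with no re-screening: pooling
matches the cross-site reference logic (a per-site sample of 5 can never
exceed 2 sample σ, since max |z| = (n−1)/√n ≈ 1.79), and a one-pass rule is
the conservative reading when no iteration rule is given. An
evaluation-year value that is itself excluded still yields a normalized
status, flagged `OUTLIER_EVAL_YEAR`; such cells can print above 100 and
should be read with the flag in hand.

## Trend confidence intervals

The 95% interval on the trend score is `5 t ± 15 se`, i.e. the slope's
standard error scaled by the same factor 5 as the slope and multiplied by a
coarse two-tailed t value of 3 at 3 degrees of freedom (the exact
t(0.975, 3) is 3.182; the method's convention keeps the round value, which
costs about a point of nominal coverage). Bounds are clamped to [−1, +1]
and flagged when the clamp binds. The trend is fit on the *normalized*
status: the reference point is constant within a window, so slope and
standard error scale identically and T is dimensionless and comparable
across services. Fewer than `min_trend_points` (default 3) in-window points
yield T = 0 with a degenerate (0, 0) interval — a two-point fit has no
estimable error.

## Conceptual model and PR scoring

Each service declares the environmental factors of the natural and social
system that push it (pressure, negative) or buffer it (resilience,
positive):

- **Quantitative factors** carry two anchors: score −1 at or below
  `lo_threshold`, +1 at or above `hi_threshold`, linear in between. The
  canonical example is dissolved oxygen for benthic food provision: −1 at
  ≤ 2 mg/L, +1 at ≥ 6 mg/L, so 4 mg/L is the pressure/resilience split and
  3 mg/L scores −0.5. `direction: decreasing_good` mirrors the line
  (score(v) ↦ −score(v)) for factors where smaller is better.
- **Qualitative factors** (blue-tide occurrence, ground stability, species
  protection, …) score ± `qualitative_magnitude` on the observed state.
  The default magnitude 0.5 — half the reach of a measured factor —
  encodes that presence/absence evidence is weaker than a measurement; it
  is configurable per factor because that halving is a provisional
  convention, not an estimate.

`PR_i` is the unweighted arithmetic mean of the scored factors. Unknown
states are *excluded* from the mean rather than scored 0: no information is
not evidence of neutrality (flag `FACTOR_UNKNOWN`). A service with no
scorable factor (e.g. a research sub-service, where a conceptual model is
not meaningful) gets PR = 0 in the projection with `PR_DEFAULTED`, so its
sustainability reflects the trend alone. By default factor states are read
at the evaluation year; `factor_years: window_mean` averages per-year
scores over the window instead.

## Clamping and NA conventions

The projection multiplier lies in [0, 2], so `x_F` can reach twice the
reference ceiling; values above 1 are clamped with `CLAMPED_FUTURE` (the
published convention never reports a score above 100, though back-solving
published tables shows the implied raw projection can exceed it — the flag
makes the choice auditable). A zero present status leaves S undefined
(`X_ZERO`, printed `–`), and a missing evaluation-year value yields an
all-NA cell (`NO_DATA`) rather than silent zeros. Ties for the reference
maximum resolve to the earliest year, then the lexicographically first
site id, so provenance is reproducible.

## Synthetic panels

`ceindex.synthetic` generates complete assessment inputs with known ground
truth. Indicator series follow `X(t) = X₀ + slope·(t − t₀) + ε`,
ε ~ N(0, σ²), truncated at zero (indicators are non-negative densities or
counts; truncation slightly biases series whose mean approaches zero), with
outliers injected as ×8 multiplicative shocks at a configurable per-
observation rate. Factor states follow declared schedules. The bundled
`tokyo_bay_like` scenario mirrors the situation the method targets: four
flats in one enclosed bay — two artificial (one small terrace structure,
one large established beach) and two natural river-mouth flats — over a
5-year window, with a food-provision service under an eight-factor
conceptual model (dissolved oxygen and chlorophyll-a quantitative, six
qualitative), a filtration service, a diversity service, and a research
service with no conceptual model. Levels and drifts are set so the
noiseless panel sits strictly inside the pooled 2σ band (screening should
catch injected shocks, not genuine cross-site contrast); chlorophyll-a
anchors are 1 and 5 µg/L, symmetric about the 3 µg/L pressure/resilience
split. Noise scales (e.g. σ = 1 g/m² on food-provision biomass) are
moderate relative to the 5-year drifts, comparable to the year-to-year
variability of real survey panels.

What the generator does *not* emulate: spatial survey-station structure
within a site, autocorrelated or non-Gaussian interannual noise, covariance
between services, and factor states that respond to the indicator series.
Passing recovery tests therefore demonstrates correctness of the scoring
arithmetic and estimators under the stated model, not robustness to messy
field data.

## Validation choices

- Trend parameter recovery runs 500 replicates of 5-point series at
  signal-to-noise 2 (slope·4/σ): the estimator mean must sit within 3
  Monte-Carlo standard errors of the truth and the ±15·se interval must
  cover it ≥ 90% of the time (the ×3 multiplier's nominal ≈ 94%).
- The screen-then-max stage is checked against a literal brute-force
  2σ oracle on random panels of ≤ 20 values.
- The algebraic identity `S = βT + (1−β)PR` is fuzzed over 10⁴ random
  unclamped tuples at 1e−9.
- The published four-flat score table is embedded as test data and checked
  for internal consistency with the score algebra (|S| ≤ 100%; back-solved
  `x = 2I/(2+S)` on-scale); its absolute values are not reproducible here
  because they rest on field-survey indicators outside this package's
  scope.

## Known limitations

Services are not weighted or aggregated across one another — a 100 in one
service is not worth a 100 in another, so no site-level total is computed.
Factor weights default to equal (a `weight` field is accepted for forward
compatibility but the aggregation is the plain mean). The trend model is a
straight line with independent Gaussian errors; five points support nothing
richer. Diversity indicators are not corrected for survey effort.
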
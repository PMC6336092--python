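# ceindex — coastal ecosystem-services index

`ceindex` scores the ecosystem services of coastal habitats — tidal flats in
particular — across multiple sites in one water body, and diagnoses which
environmental factors need countermeasures where a service is declining.
It is built for the people who run habitat construction and restoration
projects: an artificial flat is scored *relative to* nearby natural flats,
year after year, rather than against an abstract ideal.

For each service *i* at each site the package computes:

- present status `x_i = X_i / X_R`, the indicator value normalized by the
  reference point `X_R` = the maximum retained value across all compared
  sites in the most recent 5-year window (2σ outliers screened out);
- trend `T_i = 5 t_i ∈ [−1, 1]`, from the OLS slope `t_i` of the status
  series, with 95% CI `5t ± 15·se`;
- pressure–resilience `PR_i ∈ [−1, 1]`, the mean of per-factor scores from
  the service's conceptual model (quantitative factors interpolate between
  a −1 and a +1 anchor, e.g. dissolved oxygen 2→6 mg/L; qualitative factors
  score ±0.5 on presence/absence);
- near-term future status `x_{i,F} = (1 + βT_i + (1−β)PR_i)·x_i`, β = 0.67;
- service score `I_i = (x_i + x_{i,F})/2` (0–100 scale) and sustainability
  score `S_i = (x_{i,F} − x_i)/x_i` (signed percent; `S = βT + (1−β)PR`
  when nothing clamps).

A negative `S` means the service decays under present conditions; the
factor scores then name the pressures worth acting on. See
[docs/methods.md](docs/methods.md) for the full model and its conventions.

## Worked example

Generate the bundled demo — four flats in one enclosed bay (two artificial,
two natural), 2009–2013 — then score it:

```sh
cei simulate --out demo --seed 2
cei score --config demo/config.yaml --data demo --out results
```

`results/score_matrix.csv` holds the headline table, one `I/S%` cell per
service × site:

```text
service_id,A1,A2,N1,N2
food_provision,64.7/-25%,75.3/+15%,37.0/+2%,76.5/+10%
suspended_removal,93.7/-7%,58.9/+29%,46.7/+21%,23.6/+0%
research,79.6/+16%,3.3/+2%,100.0/+0%,94.6/+12%
degree_of_diversity,87.8/-4%,92.4/+0%,87.9/-2%,85.8/+20%
```

Read the first cell: at the artificial terrace flat `A1`, food provision
scores 64.7 of 100 relative to the best site-year in the bay, but its
sustainability is −25% — the service is projected to lose a quarter of its
status over the next five years under present conditions.
`results/countermeasures.csv` names the pressures behind every negative
cell (for `A1` food provision: anoxic water, blue tide, predatory species,
ground stability, lack of species protection). Every cell is fully
auditable:

```sh
cei explain --config demo/config.yaml --data demo --site A1 --service food_provision
```

```text
reference point X_R = 18.1891 (site A1, year 2009)
evaluation-year value X = 13.4812
present status x = 0.741172

trend: slope t = -0.0644786/yr, se = 0.0178257, n = 5
  T = 5t = -0.322393, 95% CI [-0.589778, -0.0550074] (bounds 5t ± 15se, clamped to [-1, 1])
...
PR = -0.1125
future status x_F = (1 + beta*T + (1-beta)*PR) * x = 0.55356
service score I = (x + x_F)/2 = 64.7366
sustainability S = (x_F - x)/x = -0.253128 (-25%)
```

The same pipeline is a library: `validate_config`, `run_assessment`, and
the stage functions (`screen_outliers`, `reference_point`, `fit_trend`,
`quantitative_factor_score`, `aggregate_pr`, …) are importable from
`ceindex`, with `ceindex.report` producing the tables above. Real
assessments supply their own `config.yaml` (schema in
[docs/config_schema.json](docs/config_schema.json)) plus tidy
`indicators.csv` / `factors.csv` files.

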
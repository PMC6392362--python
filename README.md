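# occdyn

Dynamic correlated-detection occupancy modeling with finite-mixture
detection heterogeneity, deviance partitioning, and calibration
diagnostics — built for stop-level roadside survey data (50 binary
point counts per route per year, in the style of the North American
Breeding Bird Survey) and route-by-year climate/habitat covariates.

## What it does

- **Exact likelihood** for the multi-season occupancy model in which a
  route's occupancy follows a two-state Markov chain over years
  (colonization γ, extinction ε), availability follows a Markov chain
  *along the stops* of a route (θ, θ′), and detection probabilities
  come from a two-class route-level mixture (p1, p2, weight π). All
  computations run in a scaled, log-stable vectorized form.
- **Covariate engineering**: hourly temperature interpolation from
  daily min/max (sine daytime, square-root nocturnal decay), annual
  hours above 38 °C / below 18 °C over June 1–May 31 cycles, 15-year
  trailing moving averages, NLCD-style step mapping of land-cover
  survey years, z-scoring, and the spatial-mean / temporal-deviation
  decomposition of each covariate.
- **Maximum-likelihood fitting** (multi-start quasi-Newton, numerical
  Hessian standard errors, AIC/AICc) plus the sequential
  covariate-reduction protocol (drop the smallest |estimate|/SE term,
  refit, stop when AIC rises).
- **Six-model deviance partitioning** of γ/ε structure (null, spatial,
  spatial+climate deviations, spatial+habitat deviation, both, fully
  year-varying), likelihood-ratio tests, and the explained-deviance
  ratio RDev² = (Dev_null − Dev_cov) / (Dev_null − Dev_full).
- **Goodness of fit**: Hosmer–Lemeshow calibration tests on naive
  colonization/extinction rates, with expected rates obtained by
  forward-filtering the fitted model over each route's history.
- **Synthetic data**: a fully generative counterpart of the likelihood
  (landscape gradients + trends, occupancy/availability/detection
  draws, missingness) so every stage is testable offline.

## CLI

```bash
# synthetic inputs (detections.csv, covariates.csv, truth.json)
occdyn simulate --design design.yaml --out data/ --seed 1

# covariate table from raw daily temperatures + land-cover fractions
occdyn engineer-covariates --landcover lc.csv --daily-temps temps.csv --out covariates.csv

# full pipeline: reduce nuisance structure, fit the six-model set,
# deviance partition, Hosmer-Lemeshow
occdyn run --config run.yaml

# individual stages
occdyn anodev --config run.yaml
occdyn gof --config run.yaml --rate colonization
```

`run.yaml` is a flat YAML mapping of `RunConfig` fields (unknown keys
are rejected); see `occdyn/config.py`. Outputs are per-model
coefficient CSVs, the six-model deviance table (`anodev.csv`),
Hosmer–Lemeshow bin tables, and a `summary.json` with LRTs, GOF
statistics, seeds, and a config hash.

## Layout

| module | contents |
| --- | --- |
| `occdyn.histories` | detection-history containers and validation |
| `occdyn.likelihood` | stop/season forward recursions, derived occupancy quantities |
| `occdyn.covariates` | climate/habitat covariate engineering |
| `occdyn.modelspec` / `occdyn.design` | symbolic model structure and design matrices |
| `occdyn.fitting` | MLE, standard errors, covariate reduction |
| `occdyn.anodev` | six-model set, LRTs, RDev² table |
| `occdyn.gof` | naive-rate Hosmer–Lemeshow calibration |
| `occdyn.simulate` | synthetic landscapes and datasets |
| `occdyn.io` / `occdyn.config` / `occdyn.pipeline` / `occdyn.cli` | interchange, configuration, pipeline, CLI |
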
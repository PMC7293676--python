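# spatlag

Analysis pipeline for lagged local/regional areal exposure and annual
outcome rates, exercised end-to-end on synthetic registry-style panels:

* **synth** — synthetic study regions (square-lattice areal units with queen
  adjacency), yearly exposure surfaces (east–west gradient + AR(1)-persistent
  Gaussian random field with exponential covariance, sampled by circulant
  embedding), and unbalanced outcome panels generated from a linear model in
  9 local + 9 neighborhood-mean exposure lags.
* **exposure** — grid-to-area aggregation (cell-center rule with a
  deterministic boundary tie-break), guideline threshold classification
  (strict exceedance of 10/15/25/35 µg/m³), pooled-rate merging of small
  areas, and zero-outcome filtering.
* **spatial** — queen-contiguity and inverse-distance weight matrices,
  neighborhood means, and Global Moran's I with normality / randomization /
  permutation significance.
* **design** — the 18-predictor lag design (`loc_lag_0..8`, `reg_lag_0..8`)
  and pooled Pearson correlation tables.
* **models** — five forecasting models written from scratch: closed-form
  ridge regression, NIPALS partial least squares, a CART-style regression
  tree, a model tree with ridge-stabilized linear leaves, and a convex
  combination weighted by inverse coefficient of variation of
  validation-fold errors.
* **evaluation** — seven error metrics (MSE, MAE, MAPE, Theil inequality
  coefficient, and the exact bias/variance/covariance decomposition of the
  MSE) plus a repeated random-split validation protocol with
  split-proportion sensitivity.
* **mapping** — empirical variograms (Matheron estimator), weighted
  least-squares variogram fitting (spherical/exponential), and ordinary
  kriging of predicted rates from area centroids to a raster.
* **cli** — stagewise subcommands and a fully deterministic `run-all`
  pipeline with a manifest of artifact digests.

## Command line

```bash
# full pipeline on synthetic data (simulate -> ... -> kriged forecast maps)
spatlag run-all --config config.yaml --out-dir runs/demo --seed 1

# stage by stage
spatlag simulate  --out-dir runs/sim --seed 1
spatlag aggregate --areas runs/sim/areas.geojson --grid-dir runs/sim --out panel.csv
spatlag design    --areas runs/sim/areas.geojson --exposure panel.csv \
                  --outcomes runs/sim/outcomes.csv --out design.csv
spatlag correlate --design design.csv --out correlations.csv
spatlag moran     --areas runs/sim/areas.geojson --panel runs/sim/outcomes.csv \
                  --column mortality_rate --out moran.csv
spatlag evaluate  --design design.csv --out-prefix eval --loops 50
spatlag map       --forecasts runs/demo/forecasts.csv \
                  --areas runs/sim/areas.geojson --out-dir maps/
```

Configuration is YAML, merged over built-in defaults
(`spatlag.cli.DEFAULT_CONFIG`). Example:

```yaml
generator:
  n_rows: 10
  n_cols: 10
  registry_schedule: {2006: 30, 2007: 38, 2008: 46, 2009: 54, 2010: 62,
                      2011: 70, 2012: 78, 2013: 86, 2014: 94}
weights: {kind: inverse_distance, power: 1.0}
max_lag: 8
validation: {train_fraction: 0.9, loops: 50, seed: 0}
kriging: {model: spherical, k_neighbors: 25}
seed: 0
```

`run-all` writes every intermediate artifact (GeoJSON areas, exposure and
outcome panels, lag design, correlation table, Moran results, evaluation
report, forecasts, kriged ASCII grids) plus `manifest.json` containing the
seed, config hash, per-artifact SHA-256 digests, and the combination
weights. Re-running the same config reproduces byte-identical CSVs.

## Reproducibility

Every random draw flows from a single seed through named substreams
(`numpy.random.SeedSequence` spawn keys) for the region, exposure fields,
registry entry order, outcome noise, validation splits, and permutation
tests, so each stage is individually and jointly deterministic.
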
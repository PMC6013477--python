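# seascape-sdm

Species distribution modelling for demersal fish surveyed with baited
remote underwater stereo-video (stereo-BRUV) over high-resolution
bathymetry. The package turns a bathymetry raster and a survey table of
per-site MaxN counts and fork lengths into:

1. **terrain covariates** — slope (% rise), eastness/northness of the
   slope aspect, focal relief (`range10`) and combined curvature, derived
   with Horn and Zevenbergen–Thorne stencils from the elevation grid;
2. **fitted habitat models** — generalized additive models with log
   links: negative binomial for relative abundance (MaxN, zero-rich
   counts) and gamma for individual biomass (from length-weight power
   laws W = a·L^b), each covariate entering as a small smooth (k = 4);
3. **full-subsets model selection** — every subset of ≤ 4 collinearity-
   screened covariates ranked by AICc; Akaike weights
   w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2); variable importance as the summed
   weights of models containing each covariate; best model = highest
   weight within ΔAICc < 2;
4. **validation** — 50× repeated 5-fold cross-validation reporting RMSE
   normalized by the observed response range; geographically weighted
   regression of observed on predicted with an adaptive bisquare kernel;
   Moran's I on the standardized residuals (k-nearest-neighbour weights,
   normality inference);
5. **prediction maps** — constrained (training-envelope-clamped) raster
   predictions, juvenile/mature reclassification at per-species biomass
   cutoffs, integer hotspot scores (ceiling = number of species) and
   cumulative abundance surfaces.

A seeded synthetic generator (`seascape_sdm.synthetic_data`) emulates the
target study system — a shallow embayment with discontinuous
shore-parallel ridges, ≥400 m-spaced depth-stratified sites, NB MaxN
counts and gamma biomass with smooth nonlinear terrain effects — so the
entire pipeline is testable without any field data. Rasters are ESRI
ASCII grids; tables are CSV; configs are YAML.

Intended users: fish ecologists and marine spatial planners modelling
fish–habitat associations from video surveys, and anyone needing a
tested, scriptable full-subsets GAM workflow over raster covariates.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")  # site-on-nodata notices
from seascape_sdm import (SimulationConfig, generate_bathymetry, derive_terrain,
                          sample_sites, sample_covariates, simulate_fish,
                          run_full_subsets, repeated_kfold_cv, fit_gwr,
                          morans_i, ModelSpec)

cfg = SimulationConfig(grid_shape=(300, 300), n_sites=150, min_spacing=60.0, seed=1)
grid = generate_bathymetry(cfg)                  # synthetic embayment, 4 m cells
stack = derive_terrain(grid, window_cells=10)    # six covariate layers
sites = sample_sites(grid, cfg.n_sites, cfg.min_spacing, seed=2)
cov = sample_covariates(stack, sites)
survey = simulate_fish(cov, stack, cfg.species, seed=3)

data = survey.abundance_data("species_a", cov)   # MaxN + covariates, zeros kept
cand = run_full_subsets(data, "abundance", "negative_binomial",
                        list(stack.names), max_terms=4, corr_cutoff=0.95)
print(cand.table.head(3).round(3).to_string(index=False))
print("importance:", {k: round(v, 2) for k, v in cand.variable_importance.items()})

best = cand.best_model()
spec = ModelSpec("abundance", "negative_binomial", best.predictors)
cv = repeated_kfold_cv(data, spec, seed=4, reference_fit=best)
print(f"normalized RMSE: {cv.mean_nrmse:.1f}% ± {cv.sd_nrmse:.1f}")

gwr = fit_gwr(data["response"], best.predict(data), data[["x", "y"]].to_numpy())
moran = morans_i(gwr.std_residuals, data[["x", "y"]].to_numpy(), 8)
print(f"Moran's I = {moran.I:.3f} (E[I] = {moran.expected:.3f}), p = {moran.p_value:.2f}")
```

Output:

```
                           predictors  adjusted_r2     df    aicc  delta_aicc  akaike_weight
          bathymetry+eastness+range10        0.486 10.886 455.036       0.000          0.732
bathymetry+eastness+range10+curvature        0.489 13.743 458.586       3.549          0.124
bathymetry+eastness+northness+range10        0.478 12.751 459.553       4.517          0.077
importance: {'bathymetry': 1.0, 'eastness': 1.0, 'northness': 0.08, 'slope': 0.07, 'range10': 1.0, 'curvature': 0.12}
normalized RMSE: 15.2% ± 4.4
Moran's I = -0.016 (E[I] = -0.007), p = 0.80
```

The simulated abundance truth for `species_a` is driven by bathymetry,
range10 and eastness — exactly the subset the selection recovers, with
summed Akaike weights ≈ 1 for the true covariates and ≈ 0.1 for the
noise covariates. The cross-validated error is 15% of the observed MaxN
range, and the residual Moran's I sits at its null expectation (p = 0.80):
no unexplained spatial structure.

### The whole pipeline in one call

```bash
seascape-sdm run --config config/run_example.yaml
```

writes terrain layers, survey CSVs, candidate-model and best-model
summary tables (adjusted R², df, AICc, ΔAICc, Akaike weight, normalized
RMSE per species × response), GWR residual maps, Moran's I statistics,
prediction rasters, juvenile/mature hotspot maps and a cumulative
abundance raster, plus a JSON manifest — all deterministic under the
config seed. `seascape-sdm simulate|terrain|fit` expose the individual
stages; see `--help`.

## Survey CSV schema

* `survey_sites.csv` — one row per deployment: `site_id,x,y` plus one
  `maxn_<species>` column per species.
* `survey_lengths.csv` — one row per measured individual:
  `site_id,species,fork_length_mm,sex,biomass_g`.
* species config (`config/species_example.yaml`) — per species:
  `a_male,b_male,a_female,b_female,cutoff_g` (placeholders; replace with
  published length-weight estimates).

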
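# Methods

`seascape-sdm` implements a complete species-distribution-modelling
workflow for demersal fish surveyed with baited stereo-video over
high-resolution bathymetry: terrain covariates, full-subsets GAM
selection, cross-validation and spatial residual diagnostics, and raster
prediction with life-stage hotspot scoring. This note records the models,
the numerical choices, and what the synthetic data generator does and
does not emulate.

## Terrain covariates

Six covariates describe the seafloor at each 4 m cell (cell size is a
parameter; 4 m is the default the rest of the pipeline assumes):

| layer | definition |
|---|---|
| bathymetry | elevation in m relative to datum (negative under water) |
| slope | 100·√(p² + q²) (% rise), Horn 8-neighbour gradients (p, q) |
| eastness | sin(aspect); aspect = downhill compass direction |
| northness | cos(aspect) |
| range10 | focal max − min elevation in a 10×10-cell window (1600 m² at 4 m) |
| curvature | Zevenbergen–Thorne combined profile+plan index, ESRI ×100 scaling, positive = convex |

Conventions that are genuinely open (GIS packages differ) are declared
rather than inferred: Horn gradients and the Z–T curvature stencil match
ArcGIS Spatial Analyst; flat cells (zero gradient) have undefined aspect
and get eastness = northness = 0, a neutral value for a direction that
does not exist. Derivative layers (slope, aspect-derived, curvature) are
nodata wherever any cell of the 3×3 stencil — including the centre — is
nodata or off the grid edge: a conservative rule for derivatives. The
relief window instead tolerates partial windows (≥1 valid neighbour) and
truncates at edges, a permissive rule appropriate for a range statistic.
For even window sides the window takes the extra cell up/left, matching
the `scipy.ndimage` convention. All layers share the union nodata mask.
Rasters are read and written as ESRI ASCII grids with cell-centre
registration, row 0 northernmost, nodata −9999.

## Responses

Relative abundance is MaxN, the maximum simultaneous count of a species
in any frame of a deployment — conservative because one fish can never be
counted twice. Individual biomass comes from fork length through the
power law W = a·L^b (W g, L mm), per sex where published parameters
differ; fish that cannot be sexed on video get the mean of the male and
female predictions. Length-weight coefficients and juvenile/mature
cutoffs are configuration data, never code constants. Sites keep MaxN = 0
records for abundance models; biomass models use only the measured
individuals (gamma support excludes zero). Covariates are point-sampled
at the cell containing each site — the neighbourhood structure is already
in the covariates themselves (range10, curvature).

## The GAM engine

Both families use a log link: negative binomial (NB2, Var = μ + μ²/θ)
for counts with many zeros, gamma (Var = μ²/α) for positive biomass.
Each covariate enters as a cubic B-spline smooth with basis dimension
k = 4 over the training range, centred by a sum-to-zero constraint, so
each smooth contributes at most k − 1 = 3 effective degrees of freedom —
deliberately conservative for survey-sized datasets. Coefficients are
estimated by penalized IRLS with a second-order difference penalty on
the spline coefficients; a single smoothing parameter λ shared across
smooths is selected by GCV, n·D/(n − edf)², via a coarse log-grid plus
bounded refinement. The NB θ (and gamma α) is profiled by alternating
ML updates with refits until the log-dispersion stabilises (mgcv-style
performance iteration). Effective degrees of freedom are tr[(XᵀWX +
λS)⁻¹XᵀWX]. Everything is deterministic: refits reproduce the
log-likelihood bit-for-bit. One test cross-checks the gamma fit against
R's mgcv on the same data as an independent oracle.

Fit summaries follow the conventions of the full-subsets literature:

* AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k = total effective df
  including the intercept and one dispersion/scale parameter, so NB and
  gamma models are penalized comparably. The reported `df` column is
  this same k (effective, not nominal, degrees of freedom).
* Deviance R² = 1 − D/D₀ with the null deviance computed under the
  fitted dispersion; adjusted R² = 1 − (1 − R²)(n−1)/(n−edf).

## Full-subsets selection

All subsets of at most `max_terms = 4` covariates are fitted, plus the
intercept-only model, after a collinearity screen drops any model
containing a pair with |Pearson r| above the cutoff (default 0.28, the
convention of full-subsets ecological modelling; constant columns are
conservatively excluded). Akaike weights are exp(−Δᵢ/2) normalized over
the whole set; variable importance is the summed weight of the models
containing each covariate. Within ΔAICc < 2 the model with the highest
weight wins — equivalent to lowest AICc under the weight formula — with
deterministic tie-breaks (fewer terms, then lexicographic). Models that
fail to converge are dropped with a warning rather than aborting the run.

## Validation

**Repeated k-fold CV** (default 5 folds × 50 repetitions) refits the
*selected* subset only — no re-selection inside folds — with λ and the
dispersion frozen at their full-data estimates, so folds re-estimate
coefficients alone. Held-out predictions of one repetition are pooled
into a single RMSE; the normalized RMSE divides by the full dataset's
observed range (max − min) and is reported in %. Range normalization is
the natural choice here because prediction error is judged against the
span of sampled abundance/biomass values. Fold sizes differ by at most
one; CV is bit-reproducible under a fixed seed.

**GWR** regresses observed on predicted at each site with bisquare
kernel weights; the default bandwidth is an adaptive nearest-neighbour
count chosen by leave-one-out CV over a geometric grid. Standardized
residuals are raw residuals over the global residual SD (n − 2). For
biomass, individuals are averaged to site level first (coordinates must
be distinct). As the bandwidth grows the local fits collapse onto the
global OLS line, which the tests exploit as a closed-form oracle.

**Moran's I** on the GWR standardized residuals uses row-standardized
k = 8 nearest-neighbour weights (configurable, or a user-supplied
matrix), with E[I] = −1/(n−1) and the closed-form variance under the
normality approximation for a two-sided test. Calibration on iid noise
(mean I, 5% type-I error) is verified by simulation in the test suite.

## Spatial prediction and hotspots

Selected models are evaluated at every valid cell. Prediction is
*constrained*: covariates are clamped to the training envelope, so the
smooths never extrapolate (an optional flag masks extrapolated cells
instead). Biomass rasters are reclassified at the species cutoff —
juvenile < cutoff, mature ≥ cutoff; the boundary cell counts as mature,
an arbitrary but fixed rule — and summed across species into an integer
hotspot score whose ceiling equals the species count. Juvenile and
mature scores are complementary: they sum to S at every valid cell.
Abundance rasters are summed directly (best-model predictions, not
model-averaged) into a cumulative abundance surface.

## Synthetic data generator

The generator provides the study conditions every stage is tested
under. Defaults: a 1800×1800-cell grid at 4 m (7.2 × 7.2 km), depths
−5 m nearshore to −40 m offshore, four shore-parallel sinusoidal ridge
bands (amplitude 2.5 m, wavelength 1500 m) modulated by a smooth random
field so the ridges are discontinuous, plus Gaussian-smoothed noise
(SD 0.4 m); 217 sites at least 400 m apart, dealt round-robin over four
equal-width depth strata by dart throwing. MaxN is drawn from
NB(exp(η), θ = 2) — overdispersion typical of baited-video counts, which
also produces the characteristic large zero fraction naturally — and
individual biomass from Gamma(shape = 4, mean exp(η_b)). Effects are
named curves (linear, quadratic, saturating, threshold) with log-scale
amplitudes ≈ 0.5–1.2, applied to min-max-scaled covariates; fork lengths
are the exact power-law inverse of the drawn biomass, so survey tables
round-trip.

What the generator does **not** emulate: habitat classes (seagrass,
macroalgae), bait-plume interactions between sites, fish behaviour and
detectability, measurement error in stereo lengths, and real covariate
collinearity structure beyond what the synthetic terrain induces.
Passing tests therefore demonstrate that the *statistical machinery*
recovers known structure under the assumed NB/gamma data model — not
that any particular field dataset satisfies those assumptions.

## Simulation studies and problem sizes

Three seeded studies (in `seascape_sdm.experiments`) quantify pipeline
behaviour; the test suite and `scripts/acceptance.py` run them at these
sizes, chosen to give stable Monte-Carlo estimates at desk scale:

* **Structure recovery** — 25 replicates, 200 sites on a 400×400-cell
  seascape, three true NB effects (bathymetry saturating 1.2, range10
  threshold 1.0, eastness linear 0.8, θ = 2) out of six covariates; the
  collinearity screen is relaxed to 0.95 here so the study measures
  selection, not screening, because synthetic terrain covariates are
  moderately inter-correlated by construction.
* **CV comparison** — 20 runs of 50×5-fold CV on n = 200 strong-effect
  NB data, true model vs intercept-only.
* **Moran calibration** — 500 iid-noise draws at n = 100 sites, k = 8.

The end-to-end pipeline study uses a 300×300-cell seascape with 200
sites at 60 m spacing and two species — the same generative families and
effect amplitudes as the full-size defaults, scaled spatially so the
whole run (terrain → selection → 50×5-fold CV → GWR/Moran → rasters)
stays interactive.

## Known limitations

* A single shared λ across smooths (not per-term); with k = 4 bases the
  practical difference from per-term selection is small.
* GWR uses dense distance matrices — fine for hundreds of sites, not
  thousands.
* The NB AICc treats the profiled θ as one parameter, the standard
  convention, though θ is estimated rather than fixed.
* No zero-inflated families: the NB with estimated θ is the supported
  route for zero-rich counts; interactions and spatial smooths of
  coordinates are likewise out of scope.
* ESRI ASCII is the only raster format (text-based, GIS-portable); no
  reprojection — all inputs must share one projected CRS in metres.
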
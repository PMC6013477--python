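# Full pipeline run on simulated data. Every numeric default of the
# analysis is a key here; nothing is hard-coded in the pipeline.
seed: 7
out_dir: run_output
simulate: true
simulation:
  grid_shape: [300, 300]     # cells; 4 m cell size → 1.2 km × 1.2 km
  n_sites: 120
  min_spacing: 80.0          # metres between survey sites
window_cells: 10             # relief window (10×10 cells = 1600 m² at 4 m)
predictors: [bathymetry, eastness, northness, slope, range10, curvature]
max_terms: 4                 # at most four covariates per model
basis_dim: 4                 # k = 4 basis functions per smooth
corr_cutoff: 0.95            # collinearity screen |r| threshold
cv_folds: 5
cv_repetitions: 50
moran_neighbours: 8
gwr_bandwidth: cv            # adaptive neighbour count by leave-one-out CV
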
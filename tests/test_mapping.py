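"""Raster prediction, reclassification and hotspot arithmetic."""

import warnings

import numpy as np
import pytest

from seascape_sdm.gam import fit_penalized_gam
from seascape_sdm.mapping import (PredictionRaster, cumulative_abundance,
                                  hotspot_sum, predict_raster,
                                  reclassify_biomass)
from seascape_sdm.terrain import TerrainStack


def make_raster(values, mask=None):
    values = np.asarray(values, dtype=float)
    mask = np.zeros(values.shape, bool) if mask is None else mask
    return PredictionRaster(values=values, nodata_mask=mask, cell_size=4.0,
                            origin=(0.0, 0.0))


@pytest.fixture(scope="module")
def biomass_model(request):
    world = request.getfixturevalue("sim_world")
    data = world["survey"].biomass_data("species_a", world["cov"])
    return world, fit_penalized_gam(
        data, data["response"].to_numpy(), ("bathymetry", "range10"), "gamma")


def test_prediction_positive_and_nodata_propagates(biomass_model):
    world, model = biomass_model
    raster = predict_raster(model, world["stack"])
    valid = ~raster.nodata_mask
    assert (raster.values[valid] > 0).all()
    assert np.isnan(raster.values[raster.nodata_mask]).all()
    assert np.array_equal(raster.nodata_mask, world["stack"].nodata_mask)


def test_prediction_at_training_cells_matches_fitted(biomass_model):
    world, model = biomass_model
    data = world["survey"].biomass_data("species_a", world["cov"])
    raster = predict_raster(model, world["stack"])
    grid = world["stack"].as_grid()
    r, c = grid.cell_of(data["x"].to_numpy(), data["y"].to_numpy())
    assert np.allclose(raster.values[r, c], model.fitted_values, rtol=1e-8)


def test_constant_layers_give_constant_raster(biomass_model):
    world, model = biomass_model
    stack = world["stack"]
    const_layers = {name: np.full(stack.shape, np.nanmean(layer))
                    for name, layer in stack.layers.items()}
    for arr in const_layers.values():
        arr[stack.nodata_mask] = np.nan
    const_stack = TerrainStack(const_layers, stack.cell_size, stack.origin,
                               stack.nodata_mask, stack.window_cells)
    raster = predict_raster(model, const_stack)
    vals = raster.values[~raster.nodata_mask]
    assert np.allclose(vals, vals[0], rtol=1e-12)
    point = {p: np.array([np.nanmean(stack.layers[p])])
             for p in model.predictors}
    assert vals[0] == pytest.approx(float(model.predict(point)[0]), rel=1e-12)


def test_extrapolated_covariates_clamped(biomass_model):
    world, model = biomass_model
    stack = world["stack"]
    shifted = {name: layer.copy() for name, layer in stack.layers.items()}
    shifted["bathymetry"] = shifted["bathymetry"] + 1000.0  # way above training
    hot_stack = TerrainStack(shifted, stack.cell_size, stack.origin,
                             stack.nodata_mask, stack.window_cells)
    clamped = predict_raster(model, hot_stack)
    at_max = {p: np.array([model.smooths[i].x_max])
              for i, p in enumerate(model.predictors)}
    # bathymetry pinned at its training max; range10 varies freely
    ref_stack_layers = {n: (l if n != "bathymetry" else
                            np.full_like(l, model.smooths[0].x_max))
                        for n, l in stack.layers.items()}
    ref_stack = TerrainStack(ref_stack_layers, stack.cell_size, stack.origin,
                             stack.nodata_mask, stack.window_cells)
    ref = predict_raster(model, ref_stack)
    valid = ~stack.nodata_mask
    assert np.allclose(clamped.values[valid], ref.values[valid], rtol=1e-10)


def test_mask_extrapolated_flag(biomass_model):
    world, model = biomass_model
    stack = world["stack"]
    shifted = {n: (l + 1000.0 if n == "bathymetry" else l.copy())
               for n, l in stack.layers.items()}
    hot_stack = TerrainStack(shifted, stack.cell_size, stack.origin,
                             stack.nodata_mask, stack.window_cells)
    masked = predict_raster(model, hot_stack, mask_extrapolated=True)
    assert np.isnan(masked.values[~stack.nodata_mask]).all()


def test_missing_layer_errors(biomass_model):
    world, model = biomass_model
    stack = world["stack"]
    partial = {n: l for n, l in stack.layers.items() if n != "range10"}
    broken = TerrainStack(partial, stack.cell_size, stack.origin,
                          stack.nodata_mask, stack.window_cells)
    with pytest.raises(ValueError, match="range10"):
        predict_raster(model, broken)


# ---------------------------------------------------------------------------
# Reclassification and hotspots

def test_reclassify_threshold_semantics():
    r = make_raster([[999.0, 1000.0, 1001.0]])
    juv = reclassify_biomass(r, 1000.0, "juvenile")
    mat = reclassify_biomass(r, 1000.0, "mature")
    assert juv.tolist() == [[1.0, 0.0, 0.0]]     # cell at the cutoff is mature
    assert mat.tolist() == [[0.0, 1.0, 1.0]]


def test_reclassify_rejects_bad_args():
    r = make_raster([[1.0]])
    with pytest.raises(ValueError):
        reclassify_biomass(r, -5.0, "juvenile")
    with pytest.raises(ValueError):
        reclassify_biomass(r, 10.0, "adult")


def test_hotspot_score_examples():
    ones = np.ones((4, 4))
    zeros = np.zeros((4, 4))
    assert np.all(hotspot_sum([ones, ones, ones]) == 3)
    assert np.all(hotspot_sum([zeros, zeros, zeros]) == 0)
    assert np.all(hotspot_sum([ones, zeros, ones]) == 2)


def test_hotspot_shape_mismatch_errors():
    with pytest.raises(ValueError):
        hotspot_sum([np.ones((3, 3)), np.ones((4, 4))])


def test_juvenile_plus_mature_equals_species_count(biomass_model):
    world, model = biomass_model
    raster = predict_raster(model, world["stack"])
    juvs, mats = [], []
    for cutoff in (400.0, 800.0, 1500.0):
        juvs.append(reclassify_biomass(raster, cutoff, "juvenile"))
        mats.append(reclassify_biomass(raster, cutoff, "mature"))
    total = hotspot_sum(juvs) + hotspot_sum(mats)
    valid = ~raster.nodata_mask
    assert np.all(total[valid] == 3)


def test_cumulative_abundance_sums():
    a = make_raster(np.full((3, 3), 2.0))
    b = make_raster(np.full((3, 3), 3.0))
    total = cumulative_abundance([a, b])
    assert np.all(total == 5.0)
    assert np.all(cumulative_abundance([a]) == 2.0)
    assert np.all(total >= a.values) and np.all(total >= b.values)


def test_prediction_commutes_with_subwindowing(biomass_model):
    world, model = biomass_model
    stack = world["stack"]
    full = predict_raster(model, stack)
    win = np.s_[20:80, 30:90]
    cropped = TerrainStack({n: l[win] for n, l in stack.layers.items()},
                           stack.cell_size, stack.origin,
                           stack.nodata_mask[win], stack.window_cells)
    sub = predict_raster(model, cropped)
    assert np.allclose(sub.values, full.values[win], rtol=1e-12, equal_nan=True)
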
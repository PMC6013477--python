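"""The synthetic seascape/fish generator: determinism, spacing, and
distributional agreement with the negative-binomial/gamma truth."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from seascape_sdm.survey import LengthWeightParams, length_to_biomass
from seascape_sdm.synthetic_data import (EFFECT_CURVES, SimulationConfig,
                                         SpeciesTruth, generate_bathymetry,
                                         sample_sites, simulate_fish)
from seascape_sdm.terrain import derive_terrain


def small_cfg(**kw):
    defaults = dict(grid_shape=(120, 120), n_sites=40, min_spacing=40.0, seed=5)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def intercept_only_species(intercept=1.0, theta=2.0):
    return SpeciesTruth(name="sp", effects_abundance={}, effects_biomass={},
                        intercept_abundance=intercept, intercept_biomass=6.0,
                        theta=theta)


# ---------------------------------------------------------------------------
# Bathymetry

def test_same_seed_same_grid():
    a = generate_bathymetry(small_cfg())
    b = generate_bathymetry(small_cfg())
    assert np.array_equal(a.values, b.values)
    c = generate_bathymetry(small_cfg(seed=6))
    assert not np.array_equal(a.values, c.values)


def test_zero_noise_zero_ridges_is_exact_plane():
    cfg = small_cfg(noise_sd=0.0, ridge_count=0)
    grid = generate_bathymetry(cfg)
    slope = derive_terrain(grid).layers["slope"]
    valid = ~np.isnan(slope)
    assert np.allclose(slope[valid], slope[valid].flat[0], atol=1e-9)
    # depth runs from the nearshore to the offshore configured values
    assert grid.values.max() == pytest.approx(cfg.depth_range[0], abs=1e-9)
    assert grid.values.min() == pytest.approx(cfg.depth_range[1], abs=1e-9)


def test_depth_within_construction_bounds():
    cfg = small_cfg()
    z = generate_bathymetry(cfg).values
    lo = cfg.depth_range[1] - cfg.ridge_amplitude - 4 * cfg.noise_sd
    hi = cfg.depth_range[0] + cfg.ridge_amplitude + 4 * cfg.noise_sd
    assert z.min() >= lo and z.max() <= hi


def test_bad_grid_shape_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(grid_shape=(0, 10))


# ---------------------------------------------------------------------------
# Site sampling

def test_pairwise_spacing_enforced_exhaustively():
    cfg = small_cfg()
    grid = generate_bathymetry(cfg)
    sites = sample_sites(grid, cfg.n_sites, cfg.min_spacing, seed=1)
    d = pdist(sites[["x", "y"]].to_numpy())
    assert d.min() >= cfg.min_spacing
    assert len(sites) == cfg.n_sites


def test_single_site_and_zero_spacing():
    grid = generate_bathymetry(small_cfg())
    one = sample_sites(grid, 1, 400.0, seed=2)
    assert len(one) == 1
    many = sample_sites(grid, 60, 0.0, seed=3)
    assert len(many) == 60


def test_infeasible_packing_raises():
    grid = generate_bathymetry(small_cfg())
    with pytest.raises(RuntimeError, match="fewer sites"):
        sample_sites(grid, 500, 200.0, seed=4, max_tries_per_site=20)


def test_sites_deterministic_under_seed():
    grid = generate_bathymetry(small_cfg())
    a = sample_sites(grid, 30, 40.0, seed=9)
    b = sample_sites(grid, 30, 40.0, seed=9)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# Fish simulation

@pytest.fixture(scope="module")
def flat_world():
    cfg = small_cfg(grid_shape=(200, 200), n_sites=150, min_spacing=0.0)
    grid = generate_bathymetry(cfg)
    stack = derive_terrain(grid)
    sites = sample_sites(grid, cfg.n_sites, 0.0, seed=11)
    from seascape_sdm.survey import sample_covariates
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cov = sample_covariates(stack, sites)
    return stack, cov


def test_intercept_only_mean_within_3_se(flat_world):
    stack, cov = flat_world
    sp = intercept_only_species(intercept=1.0, theta=2.0)
    # aggregate over many replicate draws for a tight LLN check
    totals, n = [], len(cov)
    for seed in range(30):
        surv = simulate_fish(cov, stack, [sp], seed=seed)
        totals.append(surv.sites["maxn_sp"].to_numpy())
    y = np.concatenate(totals)
    mu = np.exp(1.0)
    se = np.sqrt((mu + mu ** 2 / sp.theta) / len(y))
    assert abs(y.mean() - mu) < 3 * se


def test_zero_fraction_matches_nb_implied(flat_world):
    stack, cov = flat_world
    sp = intercept_only_species(intercept=0.5, theta=2.0)
    ys = [simulate_fish(cov, stack, [sp], seed=s).sites["maxn_sp"].to_numpy()
          for s in range(30)]
    y = np.concatenate(ys)
    mu = np.exp(0.5)
    p0 = (sp.theta / (sp.theta + mu)) ** sp.theta
    se = np.sqrt(p0 * (1 - p0) / len(y))
    assert abs((y == 0).mean() - p0) < 3 * se


def test_large_theta_approaches_poisson(flat_world):
    stack, cov = flat_world
    sp = intercept_only_species(intercept=1.0, theta=1e6)
    ys = [simulate_fish(cov, stack, [sp], seed=s).sites["maxn_sp"].to_numpy()
          for s in range(40)]
    y = np.concatenate(ys).astype(float)
    assert 0.8 <= y.var() / y.mean() <= 1.2


def test_biomass_positive_and_lengths_invert_exactly(flat_world):
    stack, cov = flat_world
    lw = LengthWeightParams("sp", 2e-5, 3.0, 2e-5, 3.0)
    sp = SpeciesTruth(name="sp", effects_abundance={}, effects_biomass={},
                      intercept_abundance=1.0, intercept_biomass=6.0,
                      theta=2.0, gamma_shape=4.0, lw=lw)
    surv = simulate_fish(cov, stack, [sp], seed=21)
    assert (surv.lengths["biomass_g"] > 0).all()
    recomputed = length_to_biomass(
        surv.lengths["fork_length_mm"].to_numpy(), lw, "unknown")
    assert np.allclose(recomputed, surv.lengths["biomass_g"], rtol=1e-10)
    # counts and measured individuals agree site by site
    counted = surv.lengths.groupby("site_id").size()
    maxn = surv.sites.set_index("site_id")["maxn_sp"]
    assert (maxn.loc[counted.index] == counted).all()
    assert (maxn.drop(counted.index) == 0).all()


def test_invalid_truth_rejected():
    with pytest.raises(ValueError):
        SpeciesTruth(name="sp", effects_abundance={}, effects_biomass={},
                     theta=-1.0)
    with pytest.raises(ValueError):
        SpeciesTruth(name="sp", effects_abundance={"bathymetry": ("nope", 1.0)},
                     effects_biomass={})


def test_effect_curves_bounded():
    u = np.linspace(0, 1, 101)
    for name, f in EFFECT_CURVES.items():
        vals = f(u)
        assert np.all(np.abs(vals) <= 1.0 + 1e-9), name
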
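import warnings

import numpy as np
import pytest

from seascape_sdm import (SimulationConfig, derive_terrain, generate_bathymetry,
                          sample_covariates, sample_sites, simulate_fish)


@pytest.fixture(scope="session")
def sim_world():
    """A small synthetic seascape with a simulated two-species survey.

    Shared read-only across tests; anything mutating must copy.
    """
    cfg = SimulationConfig(grid_shape=(300, 300), n_sites=100,
                           min_spacing=80.0, seed=42)
    grid = generate_bathymetry(cfg)
    stack = derive_terrain(grid)
    sites = sample_sites(grid, cfg.n_sites, cfg.min_spacing, seed=43)
    with warnings.catch_warnings():
        # sites on the stencil-nodata border ring are dropped with a warning
        warnings.simplefilter("ignore", UserWarning)
        cov = sample_covariates(stack, sites)
    survey = simulate_fish(cov, stack, cfg.species, seed=44)
    return {"cfg": cfg, "grid": grid, "stack": stack, "sites": sites,
            "cov": cov, "survey": survey}


@pytest.fixture()
def rng():
    return np.random.default_rng(20211)
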
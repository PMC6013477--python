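"""Terrain derivatives against analytic surfaces and a brute-force
per-cell stencil oracle."""

import numpy as np
import pytest

from seascape_sdm.grids import BathymetryGrid, read_ascii_grid, write_ascii_grid
from seascape_sdm.terrain import (curvature, derive_terrain, eastness,
                                  focal_range, northness, slope_aspect)

CELL = 4.0


def plane_grid(px, py, n=20, cell=CELL):
    x = np.arange(n) * cell
    xx, yy_north = np.meshgrid(x, x)
    yy = yy_north[::-1]  # row 0 = northernmost
    return BathymetryGrid(px * xx + py * yy, cell)


def interior(a):
    return a[1:-1, 1:-1]


# ---------------------------------------------------------------------------
# Analytic surfaces

@pytest.mark.parametrize("px,py,slope_exp,aspect_exp", [
    (-0.1, 0.0, 10.0, 90.0),    # dips eastward → east-facing slope
    (0.0, -0.1, 10.0, 0.0),     # dips northward → north-facing slope
    (0.1, 0.0, 10.0, 270.0),
    (-0.3, -0.4, 50.0, np.degrees(np.arctan2(0.3, 0.4))),
])
def test_slope_aspect_on_planes(px, py, slope_exp, aspect_exp):
    g = plane_grid(px, py)
    slope, aspect = slope_aspect(g)
    assert np.allclose(interior(slope), slope_exp, atol=1e-10)
    assert np.allclose(interior(aspect), aspect_exp, atol=1e-10)
    assert np.allclose(interior(curvature(g)), 0.0, atol=1e-10)


def test_constant_grid_is_flat():
    g = BathymetryGrid(np.full((10, 10), -20.0), CELL)
    slope, aspect = slope_aspect(g)
    assert np.all(interior(slope) == 0)
    assert np.isnan(interior(aspect)).all()       # flat flag
    assert np.all(interior(eastness(aspect)) == 0.0)
    assert np.all(interior(northness(aspect)) == 0.0)
    assert np.all(focal_range(g, 10) == 0.0)


@pytest.mark.parametrize("aspect,east_exp,north_exp", [
    (90.0, 1.0, 0.0), (270.0, -1.0, 0.0), (0.0, 0.0, 1.0), (180.0, 0.0, -1.0),
])
def test_eastness_northness_cardinal_directions(aspect, east_exp, north_exp):
    a = np.array([[aspect]])
    assert eastness(a)[0, 0] == pytest.approx(east_exp, abs=1e-12)
    assert northness(a)[0, 0] == pytest.approx(north_exp, abs=1e-12)


@pytest.mark.parametrize("c,expected", [(0.01, -4.0), (-0.01, 4.0)])
def test_curvature_bowl_and_dome(c, expected):
    x = np.arange(20) * CELL
    xx, yy = np.meshgrid(x, x)
    g = BathymetryGrid(c * (xx ** 2 + yy ** 2), CELL)
    assert np.allclose(interior(curvature(g)), expected, atol=1e-9)


def test_focal_range_spike():
    z = np.full((20, 20), -20.0)
    z[10, 10] = -15.0
    g = BathymetryGrid(z, CELL)
    r = focal_range(g, 5)
    assert r[10, 10] == pytest.approx(5.0)
    # the 5-cell window spans ±2 cells: col 12 still sees the spike, col 13 not
    assert r[10, 12] == pytest.approx(5.0)
    assert r[10, 13] == pytest.approx(0.0)


def test_focal_range_footprint_area():
    g = plane_grid(-0.1, 0.0)
    stack = derive_terrain(g, window_cells=10)
    footprint = (stack.window_cells * stack.cell_size) ** 2
    assert footprint == pytest.approx(1600.0)


# ---------------------------------------------------------------------------
# Brute-force per-cell stencil oracle

def brute_force_stencils(z, cell):
    """Independent per-cell Horn/Z-T stencil evaluation with python loops."""
    n, m = z.shape
    slope = np.full((n, m), np.nan)
    aspect = np.full((n, m), np.nan)
    curv = np.full((n, m), np.nan)
    for i in range(1, n - 1):
        for j in range(1, m - 1):
            win = z[i - 1:i + 2, j - 1:j + 2]
            if np.isnan(win).any():
                continue
            (a, b, c), (d, _, f), (g, h, k) = win
            p = ((c + 2 * f + k) - (a + 2 * d + g)) / (8 * cell)
            q = ((a + 2 * b + c) - (g + 2 * h + k)) / (8 * cell)
            slope[i, j] = 100 * np.sqrt(p * p + q * q)
            if slope[i, j] > 0:
                aspect[i, j] = np.degrees(np.arctan2(-p, -q)) % 360
            D = ((d + f) / 2 - win[1, 1]) / cell ** 2
            E = ((b + h) / 2 - win[1, 1]) / cell ** 2
            curv[i, j] = -2 * (D + E) * 100
    return slope, aspect, curv


def brute_force_range(z, w):
    n, m = z.shape
    out = np.full((n, m), np.nan)
    lo_off = w // 2                # even windows take the extra cell up/left
    hi_off = w - 1 - w // 2
    for i in range(n):
        for j in range(m):
            sub = z[max(i - lo_off, 0):i + hi_off + 1,
                    max(j - lo_off, 0):j + hi_off + 1]
            if np.isfinite(sub).any():
                out[i, j] = np.nanmax(sub) - np.nanmin(sub)
    return out


def test_interior_cells_match_bruteforce_oracle(rng):
    z = np.cumsum(rng.normal(0, 0.5, (20, 20)), axis=0)  # correlated relief
    g = BathymetryGrid(z, CELL)
    slope, aspect = slope_aspect(g)
    bs, ba, bc = brute_force_stencils(z, CELL)
    inner = np.s_[1:-1, 1:-1]
    assert np.allclose(slope[inner], bs[inner], atol=1e-10)
    ok = ~np.isnan(ba[inner])
    assert np.allclose(aspect[inner][ok], ba[inner][ok], atol=1e-10)
    assert np.allclose(curvature(g)[inner], bc[inner], atol=1e-10)
    for w in (3, 10):
        assert np.allclose(focal_range(g, w), brute_force_range(z, w), atol=1e-10)


# ---------------------------------------------------------------------------
# Invariants

def test_unit_circle_identity_at_nonflat_cells(rng):
    z = rng.normal(0, 1, (15, 15))
    g = BathymetryGrid(z, CELL)
    slope, aspect = slope_aspect(g)
    e, n_ = eastness(aspect), northness(aspect)
    nonflat = interior(slope) > 0
    norm = interior(e) ** 2 + interior(n_) ** 2
    assert np.allclose(norm[nonflat], 1.0, atol=1e-12)


def test_derivatives_invariant_to_vertical_shift(rng):
    z = rng.normal(-20, 2, (15, 15))
    g1 = BathymetryGrid(z, CELL)
    g2 = BathymetryGrid(z + 7.5, CELL)
    assert np.allclose(slope_aspect(g1)[0], slope_aspect(g2)[0], equal_nan=True)
    assert np.allclose(curvature(g1), curvature(g2), atol=1e-9, equal_nan=True)
    assert np.allclose(focal_range(g1, 10), focal_range(g2, 10), atol=1e-9)


def test_aspect_invariant_to_positive_rescaling(rng):
    z = rng.normal(0, 1, (15, 15))
    _, a1 = slope_aspect(BathymetryGrid(z, CELL))
    _, a2 = slope_aspect(BathymetryGrid(3.0 * z, CELL))
    assert np.allclose(a1, a2, atol=1e-10, equal_nan=True)


# ---------------------------------------------------------------------------
# Degenerate inputs and nodata

def test_small_grid_rejected():
    with pytest.raises(ValueError):
        slope_aspect(BathymetryGrid(np.zeros((2, 5)), CELL))


def test_bad_window_rejected():
    with pytest.raises(ValueError):
        focal_range(BathymetryGrid(np.zeros((5, 5)), CELL), 0)


def test_all_nodata_rejected():
    z = np.full((5, 5), np.nan)
    with pytest.raises(ValueError):
        derive_terrain(BathymetryGrid(z, CELL))


def test_nodata_propagates_through_stencils():
    z = np.zeros((10, 10)) - 0.1 * np.arange(10)[None, :] * CELL
    z[4, 4] = np.nan
    g = BathymetryGrid(z, CELL)
    slope, _ = slope_aspect(g)
    assert np.isnan(slope[3:6, 3:6]).all()     # whole 3×3 neighbourhood voided
    assert not np.isnan(slope[1, 1])
    r = focal_range(g, 3)
    assert not np.isnan(r[4, 4])               # range tolerates partial windows


def test_derive_terrain_layers_coregistered(sim_world):
    stack = sim_world["stack"]
    assert set(stack.names) == {"bathymetry", "eastness", "northness",
                                "slope", "range10", "curvature"}
    for layer in stack.layers.values():
        assert layer.shape == stack.shape
        assert np.isnan(layer[stack.nodata_mask]).all()
        assert np.isfinite(layer[~stack.nodata_mask]).all()
    assert np.all(stack.layers["slope"][~stack.nodata_mask] >= 0)
    assert np.all(stack.layers["range10"][~stack.nodata_mask] >= 0)
    e = stack.layers["eastness"][~stack.nodata_mask]
    n_ = stack.layers["northness"][~stack.nodata_mask]
    assert np.all(np.abs(e) <= 1 + 1e-12)
    assert np.all(e ** 2 + n_ ** 2 <= 1 + 1e-12)


def test_ascii_grid_roundtrip(tmp_path, rng):
    z = rng.normal(-20, 3, (12, 9))
    z[2, 3] = np.nan
    g = BathymetryGrid(z, CELL, origin=(1000.0, 2000.0))
    path = tmp_path / "bathy.asc"
    write_ascii_grid(path, g.values, g.cell_size, g.origin, g.nodata_mask,
                     fmt="%.10g")
    back = read_ascii_grid(path)
    assert back.shape == g.shape
    assert back.cell_size == g.cell_size
    assert back.origin == g.origin
    assert np.array_equal(back.nodata_mask, g.nodata_mask)
    valid = ~g.nodata_mask
    assert np.allclose(back.values[valid], g.values[valid], rtol=1e-9)
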
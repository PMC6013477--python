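"""Terrain derivatives from bathymetry.

Derives the five covariates commonly used to describe seafloor structure
in fish-habitat modelling — slope (% rise), eastness and northness of the
slope aspect, focal relief (``range10``) and combined curvature — and
assembles them with the source bathymetry into a co-registered
:class:`TerrainStack`.

Conventions
-----------
* Gradients use the Horn 8-neighbour finite-difference stencil (the
  scheme used by ArcGIS Spatial Analyst).
* Aspect is the compass direction the slope *faces* (downhill): 0° =
  north, 90° = east. Flat cells (zero gradient) carry a flat flag and
  map to eastness = northness = 0.
* Curvature is the Zevenbergen–Thorne combined (profile + plan) index
  with the ESRI ×100 scaling; positive values are upwardly convex.
* 3×3 stencil outputs are nodata wherever any neighbour is nodata or at
  the grid boundary; focal range tolerates partial windows (≥1 valid
  neighbour) and truncates at edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import BathymetryGrid

LAYER_NAMES = ("bathymetry", "eastness", "northness", "slope", "range10", "curvature")


@dataclass
class TerrainStack:
    """Named, co-registered covariate rasters sharing one nodata mask."""

    layers: dict[str, np.ndarray]
    cell_size: float
    origin: tuple[float, float]
    nodata_mask: np.ndarray
    window_cells: int = 10

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.layers.values()}
        if len(shapes) != 1:
            raise ValueError("terrain layers are not co-registered (shapes differ)")
        if self.nodata_mask.shape not in shapes:
            raise ValueError("nodata mask shape does not match layers")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nodata_mask.shape

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.layers)

    def as_grid(self) -> BathymetryGrid:
        return BathymetryGrid(self.layers["bathymetry"], self.cell_size,
                              self.origin, self.nodata_mask)


def _shifted(z: np.ndarray) -> dict[str, np.ndarray]:
    """3×3 neighbours of each interior cell, NaN-padded at the boundary.

    Keys are compass positions of the neighbour: nw n ne / w c e / sw s se
    (row 0 of the array is the northern edge).
    """
    p = np.full((z.shape[0] + 2, z.shape[1] + 2), np.nan)
    p[1:-1, 1:-1] = z
    return {
        "nw": p[:-2, :-2], "n": p[:-2, 1:-1], "ne": p[:-2, 2:],
        "w": p[1:-1, :-2], "c": p[1:-1, 1:-1], "e": p[1:-1, 2:],
        "sw": p[2:, :-2], "s": p[2:, 1:-1], "se": p[2:, 2:],
    }


def _require_3x3(grid: BathymetryGrid) -> np.ndarray:
    if grid.shape[0] < 3 or grid.shape[1] < 3:
        raise ValueError("grid must be at least 3×3 for stencil operations")
    z = grid.masked_values()
    if np.isnan(z).all():
        raise ValueError("grid holds no valid cells")
    return z


def slope_aspect(grid: BathymetryGrid) -> tuple[np.ndarray, np.ndarray]:
    """Slope (% rise) and downhill compass aspect (degrees) per cell.

    Returns
    -------
    slope : array, 100·√(p² + q²) with (p, q) the Horn gradients.
    aspect : array, degrees clockwise from north of the downhill
        direction; NaN where flat or nodata. Flatness is recoverable as
        ``slope == 0``.
    """
    z = _require_3x3(grid)
    nb = _shifted(z)
    L = grid.cell_size
    with np.errstate(invalid="ignore"):
        p = ((nb["ne"] + 2 * nb["e"] + nb["se"])
             - (nb["nw"] + 2 * nb["w"] + nb["sw"])) / (8 * L)   # dz/dx, east+
        q = ((nb["nw"] + 2 * nb["n"] + nb["ne"])
             - (nb["sw"] + 2 * nb["s"] + nb["se"])) / (8 * L)   # dz/dy, north+
        slope = 100.0 * np.hypot(p, q)
        # downhill vector is -∇z; compass angle of (east, north) components
        aspect = np.degrees(np.arctan2(-p, -q)) % 360.0
    # Horn's stencil skips the centre cell, but a cell with nodata anywhere
    # in its 3×3 neighbourhood (itself included) must stay nodata
    bad = np.isnan(sum(nb.values()))
    slope[bad] = np.nan
    aspect[(slope == 0) | bad] = np.nan
    return slope, aspect


def eastness(aspect: np.ndarray) -> np.ndarray:
    """sin(aspect): +1 east-facing, −1 west-facing; flat (NaN aspect) → 0."""
    out = np.sin(np.radians(aspect))
    return np.where(np.isnan(aspect), 0.0, out)


def northness(aspect: np.ndarray) -> np.ndarray:
    """cos(aspect): +1 north-facing, −1 south-facing; flat (NaN aspect) → 0."""
    out = np.cos(np.radians(aspect))
    return np.where(np.isnan(aspect), 0.0, out)


def focal_range(grid: BathymetryGrid, window_cells: int = 10) -> np.ndarray:
    """Focal relief: max − min elevation in a square moving window.

    The window is ``window_cells`` on a side, centred on each cell (for an
    even side the window extends one extra cell up/left), truncated at the
    grid edge. Cells whose window holds no valid neighbour are NaN.
    """
    if window_cells < 1:
        raise ValueError("window_cells must be a positive integer")
    z = grid.masked_values()
    valid = ~np.isnan(z)
    # even-sized windows: ndimage spans offsets [-(w//2), w - 1 - w//2]
    hi = ndimage.maximum_filter(np.where(valid, z, -np.inf),
                                size=window_cells, mode="constant", cval=-np.inf)
    lo = ndimage.minimum_filter(np.where(valid, z, np.inf),
                                size=window_cells, mode="constant", cval=np.inf)
    any_valid = ndimage.maximum_filter(valid.astype(np.uint8),
                                       size=window_cells, mode="constant", cval=0) > 0
    out = np.where(any_valid, hi - lo, np.nan)
    return out


def curvature(grid: BathymetryGrid) -> np.ndarray:
    """Zevenbergen–Thorne combined curvature, ESRI scaling (×100).

    −2·(D + E)·100 with D and E the second-difference coefficients of the
    quadratic surface fitted to the 3×3 window; positive = upwardly convex.
    """
    z = _require_3x3(grid)
    nb = _shifted(z)
    L2 = grid.cell_size ** 2
    with np.errstate(invalid="ignore"):
        D = ((nb["w"] + nb["e"]) / 2 - nb["c"]) / L2
        E = ((nb["n"] + nb["s"]) / 2 - nb["c"]) / L2
        curv = -2.0 * (D + E) * 100.0
    # match slope/aspect nodata: any NaN corner also voids the cell
    full = sum(nb.values())
    curv[np.isnan(full)] = np.nan
    return curv


def derive_terrain(grid: BathymetryGrid, window_cells: int = 10) -> TerrainStack:
    """Derive all six covariate layers and their union nodata mask."""
    slope, aspect = slope_aspect(grid)
    east = eastness(aspect)
    north = northness(aspect)
    # eastness/northness inherit the stencil nodata footprint from slope
    east[np.isnan(slope)] = np.nan
    north[np.isnan(slope)] = np.nan
    relief = focal_range(grid, window_cells)
    curv = curvature(grid)
    bathy = grid.masked_values()
    layers = {
        "bathymetry": bathy,
        "eastness": east,
        "northness": north,
        "slope": slope,
        "range10": relief,
        "curvature": curv,
    }
    union = np.zeros(grid.shape, dtype=bool)
    for arr in layers.values():
        union |= np.isnan(arr)
    for arr in layers.values():
        arr[union] = np.nan
    if union.all():
        raise ValueError("no cell carries a full set of terrain covariates")
    return TerrainStack(layers, grid.cell_size, grid.origin, union, window_cells)
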
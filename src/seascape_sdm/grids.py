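"""Regular-grid raster containers and plain-text raster I/O.

Rasters are square-celled, axis-aligned grids stored as 2-D float arrays
with row 0 at the northern edge (the usual file ordering). Georeferencing
is carried as the cell size plus the coordinates of the lower-left cell
*centre*, so the cell containing point (x, y) is::

    col = round((x - x0) / cell_size)
    row = (nrows - 1) - round((y - y0) / cell_size)

I/O uses the ESRI ASCII grid format (.asc), which round-trips through
plain text and is understood by every GIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_NODATA = -9999.0


@dataclass
class BathymetryGrid:
    """Gridded elevation in metres (negative below datum).

    Parameters
    ----------
    values : 2-D float array, row 0 = northernmost row.
    cell_size : cell edge length in projected metres (square cells).
    origin : (x0, y0) of the lower-left cell centre in projected metres.
    nodata_mask : boolean array, True where the cell holds no data.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata_mask shape does not match values")
            self.nodata_mask = self.nodata_mask | ~np.isfinite(self.values)
        if not np.isfinite(self.values[~self.nodata_mask]).all():
            raise ValueError("grid holds non-finite values outside the nodata mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def masked_values(self) -> np.ndarray:
        """Values with nodata cells replaced by NaN."""
        out = self.values.astype(float).copy()
        out[self.nodata_mask] = np.nan
        return out

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing points (x, y).

        Indices may fall outside the grid; callers check bounds.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.rint((x - x0) / self.cell_size).astype(int)
        row = (self.shape[0] - 1) - np.rint((y - y0) / self.cell_size).astype(int)
        return row, col

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell centre, shaped like the grid."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        xs = x0 + self.cell_size * np.arange(ncols)
        ys = y0 + self.cell_size * (nrows - 1 - np.arange(nrows))
        return np.meshgrid(xs, ys)


def read_ascii_grid(path) -> BathymetryGrid:
    """Read an ESRI ASCII grid (.asc). Supports corner or centre registration."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner",
            "xllcenter", "yllcenter", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid header missing {key!r}")
    cell = header["cellsize"]
    if "xllcenter" in header:
        x0, y0 = header["xllcenter"], header.get("yllcenter", 0.0)
    else:
        x0 = header.get("xllcorner", 0.0) + cell / 2
        y0 = header.get("yllcorner", 0.0) + cell / 2
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    values = np.loadtxt(lines[n_header:], dtype=float)
    values = np.atleast_2d(values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid body does not match header dimensions")
    mask = values == nodata
    values = values.copy()
    values[mask] = np.nan
    return BathymetryGrid(values, cell, (x0, y0), mask)


def write_ascii_grid(path, values: np.ndarray, cell_size: float,
                     origin: tuple[float, float], nodata_mask: np.ndarray | None = None,
                     nodata: float = DEFAULT_NODATA, fmt: str = "%.6g") -> None:
    """Write a layer as an ESRI ASCII grid with centre registration."""
    values = np.asarray(values, dtype=float)
    out = values.copy()
    mask = ~np.isfinite(out)
    if nodata_mask is not None:
        mask |= np.asarray(nodata_mask, dtype=bool)
    out[mask] = nodata
    nrows, ncols = out.shape
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcenter {origin[0]:.6f}\nyllcenter {origin[1]:.6f}\n"
        f"cellsize {cell_size:.6f}\nnodata_value {nodata:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)
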
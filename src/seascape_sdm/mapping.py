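"""Continuous spatial prediction and hotspot scoring.

Selected models are pushed back over the terrain stack to give a
response-scale prediction per grid cell. Predictions are *constrained*:
covariate values outside the range seen during model fitting are clamped
to the training minimum/maximum, so the map never extrapolates the
smooths (optionally such cells can be masked instead). Biomass maps are
then reclassified against a species' juvenile/mature cutoff and summed
across species into an integer hotspot score (0..S); abundance maps are
summed directly into a cumulative relative-abundance surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gam import FittedGAM
from .terrain import TerrainStack


@dataclass
class PredictionRaster:
    """Response-scale predictions per cell, with provenance metadata."""

    values: np.ndarray
    nodata_mask: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _check_coregistered(rasters) -> tuple[int, int]:
    shapes = {r.shape for r in rasters}
    if len(shapes) != 1:
        raise ValueError(f"rasters are not co-registered: shapes {sorted(shapes)}")
    return shapes.pop()


def predict_raster(model: FittedGAM, stack: TerrainStack,
                   mask_extrapolated: bool = False) -> PredictionRaster:
    """Predict a fitted GAM over every valid cell of the terrain stack.

    Covariates are clamped to the model's training envelope (constrained
    prediction); with ``mask_extrapolated=True`` cells outside the
    envelope become nodata instead.
    """
    missing = [p for p in model.predictors if p not in stack.layers]
    if missing:
        raise ValueError(f"terrain stack lacks layer(s): {missing}")
    valid = ~stack.nodata_mask
    data = {p: stack.layers[p][valid] for p in model.predictors}
    out = np.full(stack.shape, np.nan)
    n_valid = int(valid.sum())
    if model.predictors:
        pred = model.predict(data)
    else:
        pred = np.full(n_valid, float(np.exp(
            np.clip(model.coefficients[0], -30, 30))))
    out[valid] = pred
    mask = stack.nodata_mask.copy()
    if mask_extrapolated and model.predictors:
        outside = np.zeros(n_valid, dtype=bool)
        for sm in model.smooths:
            x = stack.layers[sm.name][valid]
            outside |= (x < sm.x_min) | (x > sm.x_max)
        idx = np.where(valid)
        out[idx[0][outside], idx[1][outside]] = np.nan
        mask = mask | np.isnan(out)
    return PredictionRaster(values=out, nodata_mask=mask,
                            cell_size=stack.cell_size, origin=stack.origin,
                            meta={"response": model.response_name,
                                  "family": model.family_name,
                                  "predictors": list(model.predictors)})


def reclassify_biomass(raster: PredictionRaster, cutoff_g: float,
                       side: str) -> np.ndarray:
    """Binary raster: 1 where predicted biomass falls on the given side
    of the cutoff (juvenile: < cutoff; mature: ≥ cutoff), NaN at nodata."""
    if not cutoff_g > 0:
        raise ValueError("cutoff must be positive")
    if side not in ("juvenile", "mature"):
        raise ValueError("side must be 'juvenile' or 'mature'")
    v = raster.values
    if side == "juvenile":
        cls = (v < cutoff_g).astype(float)
    else:
        cls = (v >= cutoff_g).astype(float)
    cls[raster.nodata_mask | np.isnan(v)] = np.nan
    return cls


def hotspot_sum(binary_rasters) -> np.ndarray:
    """Cellwise integer sum of per-species binary class rasters (0..S)."""
    rasters = [np.asarray(r, dtype=float) for r in binary_rasters]
    if not rasters:
        raise ValueError("no rasters to sum")
    _check_coregistered(rasters)
    total = np.zeros_like(rasters[0])
    anynan = np.zeros(rasters[0].shape, dtype=bool)
    for r in rasters:
        anynan |= np.isnan(r)
        total = total + np.nan_to_num(r)
    total[anynan] = np.nan
    return total


def cumulative_abundance(prediction_rasters) -> np.ndarray:
    """Cellwise sum of response-scale abundance predictions."""
    arrays = [r.values if isinstance(r, PredictionRaster) else np.asarray(r, float)
              for r in prediction_rasters]
    if not arrays:
        raise ValueError("no rasters to sum")
    _check_coregistered(arrays)
    total = np.zeros_like(arrays[0])
    anynan = np.zeros(arrays[0].shape, dtype=bool)
    for a in arrays:
        anynan |= np.isnan(a)
        total = total + np.nan_to_num(a)
    total[anynan] = np.nan
    return total
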
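"""Model validation: repeated k-fold cross-validation and spatial
residual diagnostics.

Cross-validation repeats a random 5-fold split (default 50 times),
refits the selected model on four folds, predicts the held-out fold on
the response scale, and pools the held-out residuals of each repetition
into one RMSE. The normalized RMSE expresses that error as a percentage
of the observed response range, making it comparable across species and
responses.

Spatial diagnostics regress observed on predicted values locally —
geographically weighted regression (GWR) with an adaptive bisquare
kernel — and test the standardized residuals for global spatial
autocorrelation with Moran's I on a row-standardized k-nearest-neighbour
weight matrix, using the normality approximation for significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .gam import FittedGAM
from .sdm_core import ModelSpec, fit_gam


# ---------------------------------------------------------------------------
# Repeated k-fold cross-validation

@dataclass
class CVResult:
    """Per-repetition pooled RMSE / normalized RMSE (%) and their summary."""

    rmse: np.ndarray
    nrmse: np.ndarray
    folds: int
    repetitions: int
    seed: int
    response_range: float

    @property
    def mean_nrmse(self) -> float:
        return float(self.nrmse.mean())

    @property
    def sd_nrmse(self) -> float:
        return float(self.nrmse.std(ddof=1)) if len(self.nrmse) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"repetition": np.arange(1, self.repetitions + 1),
                             "rmse": self.rmse, "nrmse_pct": self.nrmse})


def repeated_kfold_cv(data: pd.DataFrame, spec: ModelSpec, folds: int = 5,
                      repetitions: int = 50, seed: int = 0,
                      reference_fit: FittedGAM | None = None) -> CVResult:
    """Repeated k-fold CV of one model specification.

    Fold refits keep the smoothing parameter and dispersion frozen at
    their full-data estimates (taken from ``reference_fit`` or from a
    fresh full-data fit), so each repetition re-estimates coefficients
    only — the subset itself is fixed, with no re-selection inside folds.
    RMSE is pooled over the held-out predictions of a repetition;
    normalized RMSE divides by the full dataset's observed range.
    """
    n = len(data)
    if n < 2 * folds:
        raise ValueError(f"need at least {2 * folds} rows for {folds}-fold CV")
    y = data["response"].to_numpy(dtype=float)
    y_range = float(y.max() - y.min())
    if y_range == 0:
        raise ValueError("constant response: normalized RMSE is undefined")
    if reference_fit is None:
        reference_fit = fit_gam(data, spec)
    lam, disp = reference_fit.lam, reference_fit.dispersion

    rng = np.random.default_rng(seed)
    rmse = np.empty(repetitions)
    for rep in range(repetitions):
        order = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[order] = np.arange(n) % folds
        pred = np.empty(n)
        for f in range(folds):
            test = fold_of == f
            train = data.iloc[~test].reset_index(drop=True)
            fit = fit_gam(train, spec, lam=lam, dispersion=disp)
            pred[test] = fit.predict(data.iloc[test])
        rmse[rep] = float(np.sqrt(np.mean((y - pred) ** 2)))
    nrmse = 100.0 * rmse / y_range
    return CVResult(rmse=rmse, nrmse=nrmse, folds=folds, repetitions=repetitions,
                    seed=seed, response_range=y_range)


# ---------------------------------------------------------------------------
# Geographically weighted regression

@dataclass
class GWRResult:
    """Local observed~predicted regressions and standardized residuals."""

    intercept: np.ndarray
    slope: np.ndarray
    residuals: np.ndarray
    std_residuals: np.ndarray
    bandwidth: float            # adaptive neighbour count or fixed distance
    adaptive: bool
    kernel: str = "bisquare"

    def to_frame(self, coords: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame({
            "x": coords[:, 0], "y": coords[:, 1],
            "local_intercept": self.intercept, "local_slope": self.slope,
            "residual": self.residuals, "std_residual": self.std_residuals})


def _bisquare(d: np.ndarray, b: float) -> np.ndarray:
    w = np.zeros_like(d)
    inside = d < b
    w[inside] = (1.0 - (d[inside] / b) ** 2) ** 2
    return w


def _gwr_fit_at(i, obs, pred, w):
    """Weighted least squares of obs on pred at one site; returns (b0, b1)."""
    W = w
    X = np.column_stack([np.ones_like(pred), pred])
    XtW = X.T * W
    A = XtW @ X
    if np.linalg.cond(A) > 1e12:
        raise RuntimeError(
            f"GWR local fit singular at site index {i}; increase the bandwidth")
    return np.linalg.solve(A, XtW @ obs)


def fit_gwr(observed, predicted, coords, bandwidth="cv",
            adaptive: bool = True) -> GWRResult:
    """GWR of observed on predicted with a bisquare kernel.

    ``bandwidth`` is an adaptive nearest-neighbour count (int), a fixed
    kernel radius in map units (float with ``adaptive=False``), or
    ``'cv'`` to pick the adaptive neighbour count by leave-one-out
    cross-validation. Standardized residuals are raw residuals divided
    by the global residual standard deviation (n − 2 denominator).
    """
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    coords = np.asarray(coords, dtype=float)
    n = len(obs)
    if n < 10:
        raise ValueError("GWR needs at least 10 sites")
    if len(np.unique(coords, axis=0)) != n:
        raise ValueError("site coordinates must be distinct")
    dist = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))

    def local_preds(bw_value: float, adaptive_flag: bool, loo: bool) -> np.ndarray:
        out = np.empty(n)
        for i in range(n):
            d = dist[i]
            if adaptive_flag:
                k = int(bw_value)
                b = np.sort(d)[min(k, n - 1)]  # distance to k-th neighbour (self at 0)
                b = max(b, 1e-12)
            else:
                b = float(bw_value)
            w = _bisquare(d, b)
            if loo:
                w[i] = 0.0
            if w.sum() <= 0 or (w > 0).sum() < 3:
                raise RuntimeError(
                    f"GWR bandwidth too small at site index {i}")
            b0, b1 = _gwr_fit_at(i, obs, pred, w)
            out[i] = b0 + b1 * pred[i]
        return out

    if bandwidth == "cv":
        candidates = np.unique(np.clip(np.geomspace(10, n - 1, 8).astype(int),
                                       10, n - 1))
        scores = []
        for k in candidates:
            try:
                p = local_preds(k, True, loo=True)
                scores.append(np.sum((obs - p) ** 2))
            except RuntimeError:
                scores.append(np.inf)
        bw: float = float(candidates[int(np.argmin(scores))])
        adaptive = True
    else:
        bw = float(bandwidth)

    fitted = local_preds(bw, adaptive, loo=False)
    # local coefficients for reporting
    b0s = np.empty(n)
    b1s = np.empty(n)
    for i in range(n):
        d = dist[i]
        if adaptive:
            b = max(np.sort(d)[min(int(bw), n - 1)], 1e-12)
        else:
            b = bw
        b0s[i], b1s[i] = _gwr_fit_at(i, obs, pred, _bisquare(d, b))
    resid = obs - fitted
    sigma = float(np.sqrt(np.sum(resid ** 2) / max(n - 2, 1)))
    # near-perfect fits: treat numerically-zero scatter as zero residuals
    if sigma <= 1e-10 * max(1.0, float(np.abs(obs).max())):
        std_resid = np.zeros_like(resid)
    else:
        std_resid = resid / sigma
    return GWRResult(intercept=b0s, slope=b1s, residuals=resid,
                     std_residuals=std_resid, bandwidth=bw, adaptive=adaptive)


# ---------------------------------------------------------------------------
# Moran's I

@dataclass
class MoranResult:
    """Global Moran's I with normality-approximation inference."""

    I: float
    expected: float
    variance: float
    z_score: float
    p_value: float
    n: int


def knn_weights(coords: np.ndarray, k: int = 8) -> np.ndarray:
    """Row-standardized k-nearest-neighbour spatial weight matrix."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if k >= n:
        raise ValueError("k must be smaller than the number of sites")
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)
    W = np.zeros((n, n))
    for i in range(n):
        neigh = [j for j in idx[i] if j != i][:k]
        W[i, neigh] = 1.0 / k
    return W


def morans_i(values, coords=None, neighbours: int | np.ndarray = 8) -> MoranResult:
    """Moran's I of ``values`` under a kNN (or user-supplied) weight matrix.

    ``neighbours`` is either a neighbour count for row-standardized kNN
    weights built from ``coords``, or an explicit (n, n) weight matrix.
    Significance uses E[I] = −1/(n−1) and the closed-form variance under
    the normality assumption, with a two-sided p-value.
    """
    z = np.asarray(values, dtype=float).ravel()
    n = len(z)
    if n < 4:
        raise ValueError("Moran's I needs at least 4 observations")
    if np.ptp(z) == 0:
        raise ValueError("Moran's I is undefined for constant values")
    if isinstance(neighbours, (int, np.integer)):
        if coords is None:
            raise ValueError("coords are required to build kNN weights")
        W = knn_weights(np.asarray(coords, dtype=float), int(neighbours))
    else:
        W = np.asarray(neighbours, dtype=float)
        if W.shape != (n, n):
            raise ValueError("weight matrix shape must be (n, n)")
    zc = z - z.mean()
    S0 = W.sum()
    I = (n / S0) * float(zc @ W @ zc) / float(zc @ zc)
    EI = -1.0 / (n - 1)
    S1 = 0.5 * np.sum((W + W.T) ** 2)
    S2 = np.sum((W.sum(axis=1) + W.sum(axis=0)) ** 2)
    var = (n * n * S1 - n * S2 + 3 * S0 * S0) / (S0 * S0 * (n * n - 1)) - EI ** 2
    zscore = (I - EI) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(zscore))
    return MoranResult(I=float(I), expected=EI, variance=float(var),
                       z_score=float(zscore), p_value=float(p), n=n)
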
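"""Penalized generalized additive models with log link.

A compact GAM engine for the two response families this pipeline needs:

* negative binomial (log link) for overdispersed, zero-rich counts, with
  the dispersion parameter θ estimated by maximum likelihood;
* gamma (log link) for strictly positive continuous responses, with the
  shape parameter estimated by maximum likelihood after the mean fit.

Each predictor enters as a cubic B-spline smooth with a small basis
(``basis_dim`` functions, default 4) under a sum-to-zero constraint, so a
smooth contributes at most ``basis_dim − 1`` effective degrees of
freedom. Coefficients are estimated by penalized IRLS with a
second-order difference penalty on the spline coefficients; a single
smoothing parameter λ shared across smooths is chosen by minimizing the
GCV score n·D/(n − edf)². Effective degrees of freedom are the trace of
the penalized hat matrix.

The engine is deterministic: refitting the same data reproduces the
log-likelihood and AICc exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.interpolate import BSpline
from scipy.special import gammaln

_ETA_CLIP = 30.0


# ---------------------------------------------------------------------------
# Families

class NegativeBinomialFamily:
    """NB2 with log link: Var(μ) = μ + μ²/θ."""

    name = "negative_binomial"

    def validate(self, y: np.ndarray) -> None:
        if (y < 0).any():
            raise ValueError("abundance responses must be non-negative")
        if not np.allclose(y, np.round(y)):
            raise ValueError("abundance responses must be integer counts")

    def initial_mu(self, y: np.ndarray) -> np.ndarray:
        return y + 0.5

    def irls_weight(self, mu: np.ndarray, theta: float) -> np.ndarray:
        return mu / (1.0 + mu / theta)

    def deviance(self, y: np.ndarray, mu: np.ndarray, theta: float) -> float:
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        term2 = (y + theta) * np.log((y + theta) / (mu + theta))
        return float(2.0 * np.sum(term - term2))

    def loglik(self, y: np.ndarray, mu: np.ndarray, theta: float) -> float:
        return float(np.sum(
            gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        ))

    def initial_dispersion(self, y: np.ndarray) -> float:
        m, v = y.mean(), y.var()
        if v > m > 0:
            return float(np.clip(m * m / (v - m), 0.1, 100.0))
        return 10.0

    def estimate_dispersion(self, y: np.ndarray, mu: np.ndarray) -> float:
        res = optimize.minimize_scalar(
            lambda lt: -self.loglik(y, mu, np.exp(lt)),
            bounds=(np.log(1e-2), np.log(1e5)), method="bounded",
            options={"xatol": 1e-8})
        return float(np.exp(res.x))


class GammaFamily:
    """Gamma with log link: Var(μ) = μ²/α; α estimated post-fit by ML."""

    name = "gamma"

    def validate(self, y: np.ndarray) -> None:
        if (y <= 0).any():
            raise ValueError("biomass responses must be strictly positive")

    def initial_mu(self, y: np.ndarray) -> np.ndarray:
        return y.astype(float).copy()

    def irls_weight(self, mu: np.ndarray, shape: float) -> np.ndarray:
        return np.ones_like(mu)

    def deviance(self, y: np.ndarray, mu: np.ndarray, shape: float) -> float:
        return float(2.0 * np.sum(-np.log(y / mu) + (y - mu) / mu))

    def loglik(self, y: np.ndarray, mu: np.ndarray, shape: float) -> float:
        a = shape
        return float(np.sum(
            a * np.log(a) - a * np.log(mu) + (a - 1) * np.log(y)
            - a * y / mu - gammaln(a)
        ))

    def initial_dispersion(self, y: np.ndarray) -> float:
        return 1.0

    def estimate_dispersion(self, y: np.ndarray, mu: np.ndarray) -> float:
        res = optimize.minimize_scalar(
            lambda la: -self.loglik(y, mu, np.exp(la)),
            bounds=(np.log(1e-3), np.log(1e5)), method="bounded",
            options={"xatol": 1e-8})
        return float(np.exp(res.x))


FAMILIES = {"negative_binomial": NegativeBinomialFamily, "gamma": GammaFamily}


# ---------------------------------------------------------------------------
# Smooth terms

@dataclass
class SmoothTerm:
    """Constrained cubic B-spline basis for one predictor.

    The raw basis has ``basis_dim`` functions over the training range;
    a sum-to-zero (training-mean) constraint absorbs one dimension into
    the intercept, leaving ``basis_dim − 1`` columns. Prediction inputs
    are clamped to the training range, which doubles as the constrained
    ("training envelope") prediction rule.
    """

    name: str
    knots: np.ndarray
    transform: np.ndarray        # (basis_dim, basis_dim - 1) constraint null space
    penalty: np.ndarray          # (basis_dim - 1, basis_dim - 1)
    x_min: float
    x_max: float
    degree: int = 3

    @classmethod
    def build(cls, x: np.ndarray, name: str, basis_dim: int = 4) -> "SmoothTerm":
        x = np.asarray(x, dtype=float)
        x_min, x_max = float(x.min()), float(x.max())
        if x_max <= x_min:
            raise ValueError(f"predictor {name!r} is constant; cannot build a smooth")
        degree = 3
        n_interior = basis_dim - degree - 1
        if n_interior < 0:
            raise ValueError("basis_dim must be at least degree + 1 = 4")
        interior = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
        knots = np.concatenate([
            np.full(degree + 1, x_min), interior, np.full(degree + 1, x_max)])
        raw = BSpline.design_matrix(x, knots, degree).toarray()
        constraint = raw.mean(axis=0, keepdims=True)
        transform = linalg.null_space(constraint)
        diff = np.diff(np.eye(basis_dim), n=2, axis=0)
        penalty = transform.T @ diff.T @ diff @ transform
        return cls(name, knots, transform, penalty, x_min, x_max, degree)

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.x_min, self.x_max)
        return BSpline.design_matrix(x, self.knots, self.degree).toarray() @ self.transform

    @property
    def n_cols(self) -> int:
        return self.transform.shape[1]


# ---------------------------------------------------------------------------
# Fitted model

@dataclass
class FittedGAM:
    """A fitted log-link GAM: coefficients, bases and fit summaries.

    ``edf_total`` counts the intercept, the smooth effective degrees of
    freedom (trace of the penalized hat matrix) and one dispersion/scale
    parameter, and is the k used in AICc.
    """

    family_name: str
    predictors: tuple[str, ...]
    basis_dim: int
    coefficients: np.ndarray
    smooths: list[SmoothTerm]
    dispersion: float            # NB θ or gamma shape
    lam: float
    log_likelihood: float
    edf_model: float             # trace edf incl. intercept
    edf_smooth: dict[str, float]
    deviance: float
    null_deviance: float
    adjusted_r2: float
    n_obs: int
    fitted_values: np.ndarray
    response_name: str = "response"

    @property
    def edf_total(self) -> float:
        return self.edf_model + 1.0

    def linear_predictor(self, data: pd.DataFrame | dict) -> np.ndarray:
        X = _design_from(self.smooths, data, self.n_from(data))
        return X @ self.coefficients

    def n_from(self, data) -> int:
        if self.smooths:
            return len(np.asarray(data[self.smooths[0].name]))
        try:
            return len(data)
        except TypeError:
            return 1

    def predict(self, data: pd.DataFrame | dict) -> np.ndarray:
        """Response-scale mean; covariates clamped to the training range."""
        eta = np.clip(self.linear_predictor(data), -_ETA_CLIP, _ETA_CLIP)
        return np.exp(eta)


def _design_from(smooths: list[SmoothTerm], data, n: int) -> np.ndarray:
    cols = [np.ones((n, 1))]
    for sm in smooths:
        cols.append(sm.design(np.asarray(data[sm.name], dtype=float)))
    return np.hstack(cols)


# ---------------------------------------------------------------------------
# Fitting

def _pirls(y: np.ndarray, X: np.ndarray, P: np.ndarray, family, dispersion: float,
           max_iter: int = 60, tol: float = 1e-9):
    """Penalized IRLS for a log-link fit; returns (beta, mu, edf, deviance)."""
    mu = np.clip(family.initial_mu(y), 1e-8, None)
    eta = np.log(mu)
    dev = np.inf
    beta = None
    for _ in range(max_iter):
        z = eta + (y - mu) / mu
        w = family.irls_weight(mu, dispersion)
        XtW = X.T * w
        A = XtW @ X + P
        try:
            c, low = linalg.cho_factor(A)
            beta = linalg.cho_solve((c, low), XtW @ z)
        except linalg.LinAlgError as exc:
            raise RuntimeError("penalized IRLS normal equations are singular") from exc
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        dev_new = family.deviance(y, mu, dispersion)
        if abs(dev_new - dev) < tol * (abs(dev_new) + 0.1):
            dev = dev_new
            break
        dev = dev_new
    # edf = tr(A^{-1} X'WX) at the converged weights
    w = family.irls_weight(mu, dispersion)
    XtW = X.T * w
    A = XtW @ X + P
    c, low = linalg.cho_factor(A)
    edf = float(np.trace(linalg.cho_solve((c, low), XtW @ X)))
    return beta, mu, edf, dev


def _penalty_matrix(smooths: list[SmoothTerm], lam: float) -> np.ndarray:
    p = 1 + sum(sm.n_cols for sm in smooths)
    P = np.zeros((p, p))
    j = 1
    for sm in smooths:
        k = sm.n_cols
        P[j:j + k, j:j + k] = lam * sm.penalty
        j += k
    return P


def _select_lambda(y, X, smooths, family, dispersion) -> float:
    """Shared smoothing parameter minimizing GCV = n·D/(n − edf)²."""
    n = len(y)

    def gcv(log10_lam: float) -> float:
        P = _penalty_matrix(smooths, 10.0 ** log10_lam)
        _, _, edf, dev = _pirls(y, X, P, family, dispersion)
        denom = max(n - edf, 1e-6)
        return n * max(dev, 1e-12) / denom ** 2

    grid = np.linspace(-4.0, 6.0, 11)
    scores = [gcv(g) for g in grid]
    i = int(np.argmin(scores))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(gcv, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 0.05})
        return float(10.0 ** res.x)
    return float(10.0 ** grid[i])


def fit_penalized_gam(data, response: np.ndarray, predictors, family_name: str,
                      basis_dim: int = 4, lam: float | None = None,
                      dispersion: float | None = None,
                      response_name: str = "response") -> FittedGAM:
    """Fit a log-link GAM with one smooth per predictor.

    Parameters
    ----------
    data : table-like giving each predictor as a column/key.
    response : 1-D response vector (counts or positive reals).
    predictors : names of the covariates entering as smooths (may be
        empty for an intercept-only fit).
    family_name : 'negative_binomial' or 'gamma'.
    lam, dispersion : optionally freeze the smoothing parameter and the
        dispersion (NB θ / gamma shape) instead of estimating them —
        used by cross-validation refits.
    """
    if family_name not in FAMILIES:
        raise ValueError(f"unknown family {family_name!r}")
    family = FAMILIES[family_name]()
    y = np.asarray(response, dtype=float).ravel()
    family.validate(y)
    predictors = tuple(predictors)
    smooths = [SmoothTerm.build(np.asarray(data[p], dtype=float), p, basis_dim)
               for p in predictors]
    n = len(y)
    p_total = 1 + sum(sm.n_cols for sm in smooths)
    if n <= p_total + 1:
        raise ValueError(
            f"n = {n} too small for {p_total} coefficients plus dispersion")
    X = _design_from(smooths, data, n)

    disp = family.initial_dispersion(y) if dispersion is None else float(dispersion)
    if smooths:
        chosen_lam = _select_lambda(y, X, smooths, family, disp) if lam is None \
            else float(lam)
    else:
        chosen_lam = 0.0
    P = _penalty_matrix(smooths, chosen_lam)

    beta, mu, edf, dev = _pirls(y, X, P, family, disp)
    if dispersion is None:
        # profile the dispersion by alternating ML updates with refits
        for _ in range(5):
            new_disp = family.estimate_dispersion(y, mu)
            if abs(np.log(new_disp) - np.log(disp)) < 1e-4:
                disp = new_disp
                break
            disp = new_disp
            beta, mu, edf, dev = _pirls(y, X, P, family, disp)
        dev = family.deviance(y, mu, disp)

    ll = family.loglik(y, mu, disp)

    # null deviance under the same family and dispersion
    if smooths:
        X0 = np.ones((n, 1))
        _, mu0, _, dev0 = _pirls(y, X0, np.zeros((1, 1)), family, disp)
    else:
        dev0 = dev
    r2_dev = 1.0 - dev / dev0 if dev0 > 0 else 0.0
    denom = max(n - edf, 1e-6)
    adj_r2 = 1.0 - (1.0 - r2_dev) * (n - 1) / denom

    # per-smooth edf from the diagonal of the hat trace
    w = family.irls_weight(mu, disp)
    XtW = X.T * w
    A = XtW @ X + P
    c, low = linalg.cho_factor(A)
    hat_diag = np.diag(linalg.cho_solve((c, low), XtW @ X))
    edf_smooth = {}
    j = 1
    for sm in smooths:
        edf_smooth[sm.name] = float(hat_diag[j:j + sm.n_cols].sum())
        j += sm.n_cols

    return FittedGAM(
        family_name=family_name, predictors=predictors, basis_dim=basis_dim,
        coefficients=beta, smooths=smooths, dispersion=disp, lam=chosen_lam,
        log_likelihood=ll, edf_model=edf, edf_smooth=edf_smooth,
        deviance=dev, null_deviance=dev0, adjusted_r2=adj_r2, n_obs=n,
        fitted_values=mu, response_name=response_name)
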
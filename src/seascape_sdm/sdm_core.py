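"""Full-subsets information-theoretic model selection for fish SDMs.

Fits a GAM for every admissible subset of the terrain covariates (at
most ``max_terms`` predictors, default 4; no pair of predictors whose
Pearson correlation exceeds the collinearity cutoff, default |r| > 0.28,
the convention of the full-subsets ecology literature) plus the
intercept-only model, ranks the candidates by small-sample AICc,
converts AICc differences to Akaike weights, and scores per-covariate
importance as the sum of the weights of every model containing that
covariate. Within the ΔAICc < 2 candidate set, the model with the
highest Akaike weight is the model of best fit.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gam import FittedGAM, fit_penalized_gam

DEFAULT_CORR_CUTOFF = 0.28


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response kind, family and predictor subset."""

    response: str                      # 'abundance' | 'biomass' (label only)
    family: str                        # 'negative_binomial' | 'gamma'
    predictors: tuple[str, ...]
    basis_dim: int = 4

    def __post_init__(self) -> None:
        if self.family not in ("negative_binomial", "gamma"):
            raise ValueError(f"unsupported family {self.family!r}")


@dataclass
class CandidateModelTable:
    """All fitted subsets with their AICc ranking and variable importance.

    ``table`` columns: predictors ('+'-joined, empty string = null
    model), adjusted_r2, df, aicc, delta_aicc, akaike_weight. Weights
    sum to 1 over the table and min(delta_aicc) = 0.
    """

    table: pd.DataFrame
    variable_importance: dict[str, float]
    models: dict[tuple[str, ...], FittedGAM] = field(default_factory=dict)
    failures: list[tuple[tuple[str, ...], str]] = field(default_factory=list)

    def best(self, delta_threshold: float = 2.0) -> pd.Series:
        return rank_and_select(self.table, delta_threshold)

    def best_model(self, delta_threshold: float = 2.0) -> FittedGAM:
        row = self.best(delta_threshold)
        key = tuple(p for p in row["predictors"].split("+") if p)
        return self.models[key]

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def screen_collinearity(covariates: pd.DataFrame,
                        cutoff: float = DEFAULT_CORR_CUTOFF) -> set[frozenset[str]]:
    """Unordered predictor pairs with |Pearson r| > cutoff.

    Constant columns have undefined correlations; every pair involving
    one is flagged (excluded) conservatively.
    """
    if len(covariates) < 3:
        raise ValueError("need at least 3 rows to screen collinearity")
    cols = list(covariates.columns)
    excluded: set[frozenset[str]] = set()
    values = covariates.to_numpy(dtype=float)
    sd = values.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    for i, j in itertools.combinations(range(len(cols)), 2):
        if sd[i] == 0 or sd[j] == 0 or np.isnan(corr[i, j]):
            excluded.add(frozenset((cols[i], cols[j])))
        elif abs(corr[i, j]) > cutoff:
            excluded.add(frozenset((cols[i], cols[j])))
    return excluded


def enumerate_candidate_models(predictors, max_terms: int = 4,
                               excluded_pairs: set[frozenset[str]] | None = None
                               ) -> list[tuple[str, ...]]:
    """All predictor subsets of size 1..max_terms containing no excluded
    pair, plus the intercept-only model (the empty tuple), in a
    deterministic order."""
    if max_terms < 1:
        raise ValueError("max_terms must be at least 1")
    excluded_pairs = excluded_pairs or set()
    predictors = list(predictors)
    subsets: list[tuple[str, ...]] = [()]
    for size in range(1, min(max_terms, len(predictors)) + 1):
        for combo in itertools.combinations(predictors, size):
            if any(frozenset(pair) in excluded_pairs
                   for pair in itertools.combinations(combo, 2)):
                continue
            subsets.append(combo)
    return subsets


def aicc(log_likelihood: float, k: float, n: int) -> float:
    """AICc = −2ℓ + 2k + 2k(k+1)/(n − k − 1); k may be fractional (edf)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n = {n} ≤ k + 1 = {k + 1}")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """exp(−Δᵢ/2) normalized over the candidate set."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0 or not np.isfinite(a).all():
        raise ValueError("AICc values must be non-empty and finite")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def rank_and_select(table: pd.DataFrame, delta_threshold: float = 2.0) -> pd.Series:
    """Best row: highest Akaike weight within ΔAICc < threshold.

    Ties break deterministically toward fewer predictors, then
    lexicographic predictor order.
    """
    if len(table) == 0:
        raise ValueError("empty candidate model table")
    cand = table[table["delta_aicc"] < delta_threshold]
    if len(cand) == 0:       # guard: the ΔAICc = 0 row is always < threshold
        cand = table
    def n_terms(s: str) -> int:
        return 0 if s == "" else s.count("+") + 1
    cand = cand.iloc[np.lexsort((
        cand["predictors"].to_numpy(),
        [n_terms(s) for s in cand["predictors"]],
        -cand["akaike_weight"].to_numpy(),
    ))]
    return cand.iloc[0]


def variable_importance(table: pd.DataFrame, predictors) -> dict[str, float]:
    """Summed Akaike weights of the models containing each covariate."""
    vi = {p: 0.0 for p in predictors}
    for _, row in table.iterrows():
        terms = [t for t in row["predictors"].split("+") if t]
        for t in terms:
            if t in vi:
                vi[t] += float(row["akaike_weight"])
    return vi


def fit_gam(data: pd.DataFrame, spec: ModelSpec, *, lam: float | None = None,
            dispersion: float | None = None) -> FittedGAM:
    """Fit one candidate GAM given a data table with a 'response' column."""
    family = spec.family
    return fit_penalized_gam(data, data["response"].to_numpy(), spec.predictors,
                             family, basis_dim=spec.basis_dim,
                             lam=lam, dispersion=dispersion,
                             response_name=spec.response)


def run_full_subsets(data: pd.DataFrame, response: str, family: str,
                     predictors, max_terms: int = 4, basis_dim: int = 4,
                     corr_cutoff: float = DEFAULT_CORR_CUTOFF) -> CandidateModelTable:
    """Fit every admissible predictor subset and assemble the ranking.

    ``data`` holds a 'response' column plus one column per covariate.
    Models that fail to fit are dropped with a warning and recorded in
    ``failures``; if every fit fails the run errors out.
    """
    predictors = list(predictors)
    excluded = screen_collinearity(data[predictors], corr_cutoff)
    subsets = enumerate_candidate_models(predictors, max_terms, excluded)
    n = len(data)
    rows = []
    models: dict[tuple[str, ...], FittedGAM] = {}
    failures: list[tuple[tuple[str, ...], str]] = []
    for subset in subsets:
        spec = ModelSpec(response=response, family=family,
                         predictors=subset, basis_dim=basis_dim)
        try:
            fit = fit_gam(data, spec)
            value = aicc(fit.log_likelihood, fit.edf_total, n)
        except Exception as exc:  # noqa: BLE001 - any fit failure is recorded
            failures.append((subset, str(exc)))
            warnings.warn(f"model {'+'.join(subset) or '(null)'} failed: {exc}",
                          stacklevel=2)
            continue
        models[subset] = fit
        rows.append({
            "predictors": "+".join(subset),
            "adjusted_r2": fit.adjusted_r2,
            "df": fit.edf_total,
            "aicc": value,
        })
    if not rows:
        raise RuntimeError("every candidate model failed to fit")
    table = pd.DataFrame(rows)
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    table["akaike_weight"] = akaike_weights(table["aicc"].to_numpy())
    table = table.sort_values("aicc", kind="stable").reset_index(drop=True)
    vi = variable_importance(table, predictors)
    return CandidateModelTable(table=table, variable_importance=vi,
                               models=models, failures=failures)
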
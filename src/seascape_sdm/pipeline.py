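"""End-to-end orchestration: terrain → survey → selection → validation → maps.

A single config (YAML file or dict) drives one logged, seeded run over
every species × response. Outputs are plain-text artifacts under the run
directory: ESRI ASCII rasters for terrain, predictions and hotspot
scores; CSVs for the survey, candidate-model rankings, the best-model
summary table and cross-validation; JSON for spatial diagnostics and the
run manifest.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grids import read_ascii_grid, write_ascii_grid
from .mapping import (cumulative_abundance, hotspot_sum, predict_raster,
                      reclassify_biomass)
from .sdm_core import ModelSpec, run_full_subsets
from .survey import SurveyTable, sample_covariates
from .synthetic_data import SimulationConfig, generate_bathymetry, sample_sites, \
    simulate_fish
from .terrain import LAYER_NAMES, derive_terrain
from .validation import fit_gwr, morans_i, repeated_kfold_cv

log = logging.getLogger("seascape_sdm")

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "run_output",
    "simulate": True,
    "bathymetry": None,          # path to .asc when simulate is false
    "simulation": {},            # overrides for SimulationConfig fields
    "window_cells": 10,
    "predictors": list(LAYER_NAMES),
    "max_terms": 4,
    "basis_dim": 4,
    "corr_cutoff": 0.28,
    "cv_folds": 5,
    "cv_repetitions": 50,
    "moran_neighbours": 8,
    "gwr_bandwidth": "cv",
}


@dataclass
class RunManifest:
    """What a run produced: config snapshot, seeds, outputs, warnings."""

    config: dict
    seed: int
    version: str
    outputs: dict[str, str] = field(default_factory=dict)
    stage_status: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial manifest."""

    def __init__(self, stage: str, manifest: RunManifest, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    merged = dict(DEFAULT_CONFIG)
    merged.update(config or {})
    return merged


def _float_fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df.round(10)


def run_all(config) -> RunManifest:
    """Execute the full analysis described by ``config``; see
    ``DEFAULT_CONFIG`` for keys. Returns the run manifest; any stage
    failure raises :class:`StageError` carrying the partial manifest."""
    cfg = _load_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = RunManifest(config=cfg, seed=seed, version=__version__)
    caught: list[str] = []

    def record(stage: str) -> None:
        manifest.stage_status[stage] = "ok"
        log.info("stage %s: ok", stage)

    stage = "terrain"
    try:
        sim_overrides = dict(cfg.get("simulation") or {})
        if cfg["simulate"]:
            sim_cfg = SimulationConfig(seed=seed, **sim_overrides)
            grid = generate_bathymetry(sim_cfg)
        else:
            if not cfg.get("bathymetry"):
                raise ValueError("config key 'bathymetry' is required when "
                                 "simulate is false")
            grid = read_ascii_grid(cfg["bathymetry"])
            sim_cfg = None
        stack = derive_terrain(grid, int(cfg["window_cells"]))
        for name, layer in stack.layers.items():
            p = out / f"terrain_{name}.asc"
            write_ascii_grid(p, layer, stack.cell_size, stack.origin,
                             stack.nodata_mask)
            manifest.outputs[f"terrain_{name}"] = str(p)
        record(stage)

        stage = "survey"
        if cfg["simulate"]:
            sites = sample_sites(grid, sim_cfg.n_sites, sim_cfg.min_spacing,
                                 seed=seed + 1, n_strata=sim_cfg.n_depth_strata)
            cov = sample_covariates(stack, sites)
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                survey = simulate_fish(cov, stack, sim_cfg.species, seed=seed + 2)
            caught += [str(w.message) for w in wlist]
            species_names = [sp.name for sp in sim_cfg.species]
            cutoffs = {sp.name: (sp.lw.cutoff_g if sp.lw else 1000.0)
                       for sp in sim_cfg.species}
        else:
            survey = SurveyTable.read_csv(cfg["sites_csv"], cfg["lengths_csv"])
            cov = sample_covariates(stack, survey.sites)
            species_names = survey.species
            cutoffs = {s: float(c) for s, c in (cfg.get("cutoffs_g") or {}).items()}
        survey.write_csv(out / "survey_sites.csv", out / "survey_lengths.csv")
        cov.to_csv(out / "site_covariates.csv", index=False)
        manifest.outputs["survey_sites"] = str(out / "survey_sites.csv")
        manifest.outputs["survey_lengths"] = str(out / "survey_lengths.csv")
        record(stage)

        predictors = list(cfg["predictors"])
        summary_rows = []
        abundance_rasters = []
        juvenile_maps, mature_maps = [], []
        moran_report = {}

        for sp_name in species_names:
            for response, family in (("abundance", "negative_binomial"),
                                     ("biomass", "gamma")):
                stage = f"model:{sp_name}:{response}"
                if response == "abundance":
                    data = survey.abundance_data(sp_name, cov)
                else:
                    data = survey.biomass_data(sp_name, cov)
                if len(data) < 4 * int(cfg["cv_folds"]):
                    manifest.stage_status[stage] = "skipped: too few records"
                    caught.append(f"{stage}: skipped ({len(data)} records)")
                    continue
                with warnings.catch_warnings(record=True) as wlist:
                    warnings.simplefilter("always")
                    cand = run_full_subsets(
                        data, response, family, predictors,
                        max_terms=int(cfg["max_terms"]),
                        basis_dim=int(cfg["basis_dim"]),
                        corr_cutoff=float(cfg["corr_cutoff"]))
                caught += [str(w.message) for w in wlist]
                cand_path = out / f"candidates_{sp_name}_{response}.csv"
                _float_fmt(cand.table).to_csv(cand_path, index=False)
                manifest.outputs[f"candidates_{sp_name}_{response}"] = str(cand_path)
                vi_path = out / f"importance_{sp_name}_{response}.csv"
                pd.Series(cand.variable_importance).rename("summed_weight") \
                    .to_csv(vi_path, index_label="predictor")
                best_row = cand.best()
                best = cand.best_model()

                stage = f"validate:{sp_name}:{response}"
                spec = ModelSpec(response=response, family=family,
                                 predictors=best.predictors,
                                 basis_dim=int(cfg["basis_dim"]))
                cv = repeated_kfold_cv(data, spec, folds=int(cfg["cv_folds"]),
                                       repetitions=int(cfg["cv_repetitions"]),
                                       seed=seed + 3, reference_fit=best)
                cv.to_frame().to_csv(out / f"cv_{sp_name}_{response}.csv",
                                     index=False)
                # site-level observed vs predicted for spatial diagnostics
                agg = {p: (p, "first") for p in predictors if p in data.columns}
                site_df = data.groupby(["x", "y"], as_index=False).agg(
                    observed=("response", "mean"), **agg)
                site_pred = best.predict(site_df) if best.predictors else \
                    np.full(len(site_df), best.fitted_values.mean())
                gwr = fit_gwr(site_df["observed"], site_pred,
                              site_df[["x", "y"]].to_numpy(),
                              bandwidth=cfg["gwr_bandwidth"])
                res_df = gwr.to_frame(site_df[["x", "y"]].to_numpy())
                res_df.to_csv(out / f"gwr_residuals_{sp_name}_{response}.csv",
                              index=False)
                moran = morans_i(gwr.std_residuals,
                                 site_df[["x", "y"]].to_numpy(),
                                 int(cfg["moran_neighbours"]))
                moran_report[f"{sp_name}_{response}"] = {
                    "I": moran.I, "expected": moran.expected,
                    "z_score": moran.z_score, "p_value": moran.p_value}

                stage = f"map:{sp_name}:{response}"
                raster = predict_raster(best, stack)
                rp = out / f"prediction_{sp_name}_{response}.asc"
                write_ascii_grid(rp, raster.values, raster.cell_size,
                                 raster.origin, raster.nodata_mask)
                manifest.outputs[f"prediction_{sp_name}_{response}"] = str(rp)
                if response == "abundance":
                    abundance_rasters.append(raster)
                else:
                    cut = cutoffs.get(sp_name, 1000.0)
                    juvenile_maps.append(reclassify_biomass(raster, cut, "juvenile"))
                    mature_maps.append(reclassify_biomass(raster, cut, "mature"))

                summary_rows.append({
                    "species": sp_name, "response": response,
                    "intercept": float(best.coefficients[0]),
                    **{p: "+" if p in best.predictors else ""
                       for p in predictors},
                    "adjusted_r2": round(best.adjusted_r2, 6),
                    "df": round(best.edf_total, 6),
                    "aicc": round(float(best_row["aicc"]), 6),
                    "delta_aicc": round(float(best_row["delta_aicc"]), 6),
                    "akaike_weight": round(float(best_row["akaike_weight"]), 6),
                    "normalized_rmse_pct": round(cv.mean_nrmse, 6),
                })
                record(stage)

        stage = "hotspots"
        if juvenile_maps:
            for label, maps in (("juvenile", juvenile_maps),
                                ("mature", mature_maps)):
                score = hotspot_sum(maps)
                p = out / f"hotspot_{label}.asc"
                write_ascii_grid(p, score, stack.cell_size, stack.origin,
                                 stack.nodata_mask, fmt="%.0f")
                manifest.outputs[f"hotspot_{label}"] = str(p)
        if abundance_rasters:
            cum = cumulative_abundance(abundance_rasters)
            p = out / "cumulative_abundance.asc"
            write_ascii_grid(p, cum, stack.cell_size, stack.origin,
                             stack.nodata_mask)
            manifest.outputs["cumulative_abundance"] = str(p)
        record(stage)

        stage = "summary"
        summary = pd.DataFrame(summary_rows)
        summary.to_csv(out / "best_models_summary.csv", index=False)
        manifest.outputs["best_models_summary"] = str(out / "best_models_summary.csv")
        with open(out / "moran.json", "w") as fh:
            json.dump(moran_report, fh, indent=2)
        manifest.outputs["moran"] = str(out / "moran.json")
        record(stage)
    except StageError:
        raise
    except Exception as exc:
        manifest.stage_status[stage] = f"failed: {exc}"
        manifest.warnings = caught
        manifest.write(out / "manifest.json")
        raise StageError(stage, manifest, exc) from exc

    manifest.warnings = caught
    manifest.write(out / "manifest.json")
    manifest.outputs["manifest"] = str(out / "manifest.json")
    return manifest
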
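"""Survey responses: MaxN relative abundance and length-derived biomass.

Baited stereo-video surveys index relative abundance by MaxN — the
maximum number of individuals of a species visible in any single frame
of a deployment, a conservative count that avoids re-counting the same
fish. Fork lengths of the individuals present at MaxN are converted to
individual biomass through species- and sex-specific power-law
length-weight relationships W = a·L^b (W in grams, L in millimetres).
When a fish cannot be sexed from video, the male and female predictions
are averaged.

The module also joins terrain covariates onto sites by point lookup of
the raster cell containing each deployment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .terrain import TerrainStack

LENGTH_COLUMNS = ["site_id", "species", "fork_length_mm", "sex", "biomass_g"]


@dataclass(frozen=True)
class LengthWeightParams:
    """Power-law length-weight coefficients, per sex, and the biomass
    cutoff (g) separating juveniles from mature adults.

    Monomorphic species simply repeat the same coefficients for both
    sexes. Values ship in config as data — they come from the fisheries
    literature for each species, never from code constants.
    """

    species: str
    a_male: float
    b_male: float
    a_female: float
    b_female: float
    cutoff_g: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("a_male", "b_male", "a_female", "b_female"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def load_species_config(path) -> dict[str, LengthWeightParams]:
    """Load a YAML mapping species → length-weight params and cutoff."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for species, p in raw.items():
        out[species] = LengthWeightParams(
            species=species,
            a_male=float(p["a_male"]), b_male=float(p["b_male"]),
            a_female=float(p["a_female"]), b_female=float(p["b_female"]),
            cutoff_g=float(p.get("cutoff_g", 1000.0)),
        )
    return out


def maxn_from_counts(frame_counts) -> int:
    """MaxN: the maximum simultaneous count over a deployment's frames."""
    counts = list(frame_counts)
    if len(counts) == 0:
        raise ValueError("frame_counts must be a non-empty sequence")
    arr = np.asarray(counts)
    if (arr < 0).any():
        raise ValueError("frame counts must be non-negative")
    return int(arr.max())


def length_to_biomass(length_mm, params: LengthWeightParams, sex: str = "unknown"):
    """Biomass in grams from fork length via W = a·L^b.

    ``sex`` is 'male', 'female' or 'unknown'; unknown-sex fish get the
    arithmetic mean of the male and female predictions.
    """
    length = np.asarray(length_mm, dtype=float)
    if not (length > 0).all():
        raise ValueError("fork length must be positive")
    male = params.a_male * length ** params.b_male
    female = params.a_female * length ** params.b_female
    if sex == "male":
        out = male
    elif sex == "female":
        out = female
    elif sex == "unknown":
        out = (male + female) / 2.0
    else:
        raise ValueError(f"unknown sex category: {sex!r}")
    return out if out.ndim else float(out)


def biomass_from_lengths(lengths: pd.DataFrame,
                         config: dict[str, LengthWeightParams]) -> pd.DataFrame:
    """Append a ``biomass_g`` column to a long-format length table.

    Expects columns site_id, species, fork_length_mm and optionally sex
    (default 'unknown').
    """
    lengths = lengths.copy()
    if "sex" not in lengths.columns:
        lengths["sex"] = "unknown"
    biomass = np.empty(len(lengths))
    for (species, sex), idx in lengths.groupby(["species", "sex"]).groups.items():
        if species not in config:
            raise KeyError(f"no length-weight parameters for species {species!r}")
        biomass[lengths.index.get_indexer(idx)] = length_to_biomass(
            lengths.loc[idx, "fork_length_mm"].to_numpy(), config[species], sex)
    lengths["biomass_g"] = biomass
    return lengths


def sample_covariates(stack: TerrainStack, sites: pd.DataFrame) -> pd.DataFrame:
    """Terrain covariates of the raster cell containing each site.

    ``sites`` needs columns site_id, x, y. Sites falling on nodata cells
    are dropped with a warning; sites outside the raster extent raise,
    naming the offenders.
    """
    grid = stack.as_grid()
    row, col = grid.cell_of(sites["x"].to_numpy(), sites["y"].to_numpy())
    nrows, ncols = stack.shape
    outside = (row < 0) | (row >= nrows) | (col < 0) | (col >= ncols)
    if outside.any():
        bad = sites.loc[outside, "site_id"].tolist()
        raise ValueError(f"sites outside raster extent: {bad}")
    on_nodata = stack.nodata_mask[row, col]
    if on_nodata.any():
        warnings.warn(
            f"excluded {int(on_nodata.sum())} site(s) on nodata cells: "
            f"{sites.loc[on_nodata, 'site_id'].tolist()}", stacklevel=2)
    keep = ~on_nodata
    out = pd.DataFrame({"site_id": sites.loc[keep, "site_id"].to_numpy(),
                        "x": sites.loc[keep, "x"].to_numpy(),
                        "y": sites.loc[keep, "y"].to_numpy()})
    for name, layer in stack.layers.items():
        out[name] = layer[row[keep], col[keep]]
    return out


@dataclass
class SurveyTable:
    """Per-site MaxN (wide) plus per-individual lengths/biomass (long).

    ``sites``: site_id, x, y, one ``maxn_<species>`` column per species.
    ``lengths``: site_id, species, fork_length_mm, sex, biomass_g.

    Invariant: a site has measured lengths for a species only if its
    MaxN is positive, and never more lengths than MaxN.
    """

    sites: pd.DataFrame
    lengths: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.lengths.groupby(["site_id", "species"]).size()
        for (site, species), n in counts.items():
            maxn_col = f"maxn_{species}"
            if maxn_col not in self.sites.columns:
                raise ValueError(f"lengths reference unknown species {species!r}")
            maxn = self.sites.loc[self.sites["site_id"] == site, maxn_col]
            if len(maxn) == 0:
                raise ValueError(f"lengths reference unknown site {site!r}")
            if n > int(maxn.iloc[0]):
                raise ValueError(
                    f"site {site!r}, species {species!r}: {n} lengths exceed MaxN")

    @property
    def species(self) -> list[str]:
        return [c.removeprefix("maxn_") for c in self.sites.columns
                if c.startswith("maxn_")]

    def write_csv(self, sites_path, lengths_path) -> None:
        self.sites.to_csv(sites_path, index=False)
        self.lengths.to_csv(lengths_path, index=False)

    @classmethod
    def read_csv(cls, sites_path, lengths_path) -> "SurveyTable":
        return cls(pd.read_csv(sites_path), pd.read_csv(lengths_path))

    def abundance_data(self, species: str, covariates: pd.DataFrame) -> pd.DataFrame:
        """Per-site MaxN joined with covariates (keeps zeros)."""
        col = f"maxn_{species}"
        if col not in self.sites.columns:
            raise KeyError(f"no MaxN column for species {species!r}")
        df = covariates.merge(self.sites[["site_id", col]], on="site_id")
        return df.rename(columns={col: "response"})

    def biomass_data(self, species: str, covariates: pd.DataFrame) -> pd.DataFrame:
        """Per-individual biomass joined with the site's covariates."""
        sub = self.lengths[self.lengths["species"] == species]
        df = sub.merge(covariates, on="site_id", suffixes=("_fish", ""))
        df = df[df["biomass_g"] > 0]
        return df.rename(columns={"biomass_g": "response"})
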
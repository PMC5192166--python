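"""Core data containers for elevational-gradient analyses.

The two central objects are :class:`SiteTable` (the predictor side: sites
with elevation, habitat and environmental covariates) and
:class:`TaxonCommunity` (the response side: one taxonomic group's
site-by-species abundance matrix).  Both are thin, validated wrappers around
pandas DataFrames so that every downstream stage can rely on their
invariants instead of re-checking raw tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: Covariate columns recognised by the standard analyses.
STANDARD_COVARIATES = ("MAT", "MMT", "MAP", "NPP", "area")

REQUIRED_SITE_COLUMNS = ("site_id", "elevation_m")


class ValidationError(ValueError):
    """Raised when a table violates a container invariant."""


@dataclass
class SiteTable:
    """Study sites along an elevational gradient.

    Parameters
    ----------
    data
        One row per site.  Required columns: ``site_id`` (unique identifier)
        and ``elevation_m`` (metres a.s.l., strictly positive and unique).
        Optional covariates: ``habitat`` (categorical), ``MAT``/``MMT``
        (mean annual / mean minimum temperature, °C), ``MAP`` (mean annual
        precipitation, mm yr⁻¹), ``NPP`` (productivity index in [0, 1]),
        ``area`` (land area, km²).  Later stages may append derived columns
        such as ``MDE`` (null-model predicted richness) and ``PSR`` (plant
        species richness).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in REQUIRED_SITE_COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"site table is missing required column {col!r}")
        if df["site_id"].duplicated().any():
            dupes = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
            raise ValidationError(f"duplicated site_id values: {dupes}")
        elev = df["elevation_m"].to_numpy(dtype=float)
        if not np.all(np.isfinite(elev)) or np.any(elev <= 0):
            raise ValidationError("elevation_m must be finite and strictly positive")
        if len(np.unique(elev)) != len(elev):
            raise ValidationError("elevation_m must be unique per site")
        for col in df.columns:
            if col in ("site_id", "habitat"):
                continue
            vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
            observed = df[col].notna().to_numpy()
            if np.any(observed & ~np.isfinite(np.where(observed, vals, 0.0))):
                raise ValidationError(f"non-finite values in covariate {col!r}")
        if "MAT" in df.columns and "MMT" in df.columns:
            both = df["MAT"].notna() & df["MMT"].notna()
            if (df.loc[both, "MMT"] > df.loc[both, "MAT"] + 1e-9).any():
                raise ValidationError("MMT exceeds MAT on some sites")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def site_ids(self) -> list:
        return self.data["site_id"].tolist()

    @property
    def elevations(self) -> np.ndarray:
        """Site elevations (m a.s.l.) as a float array."""
        return self.data["elevation_m"].to_numpy(dtype=float)

    def covariate(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise KeyError(f"covariate {name!r} not in site table")
        return self.data[name].to_numpy(dtype=float)

    def with_column(self, name: str, values) -> "SiteTable":
        """Return a copy with a derived column appended (e.g. MDE, PSR)."""
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self),):
            raise ValidationError(
                f"column {name!r} has length {values.shape}, expected {len(self)}"
            )
        df = self.data.copy()
        df[name] = values
        return SiteTable(df)


@dataclass
class TaxonCommunity:
    """One taxonomic group's site-by-species abundance matrix.

    ``matrix`` has sites as rows (indexed by site_id, in the same order as
    the associated :class:`SiteTable`) and species as columns; cells are
    non-negative integer counts.  ``is_census`` marks completely censused
    groups recorded as presence/absence, for which abundance-based
    estimators (Chao1, coverage, rarefaction) are refused.
    """

    taxon_name: str
    kingdom: str
    matrix: pd.DataFrame
    is_census: bool = False

    def __post_init__(self) -> None:
        if self.kingdom not in ("plant", "animal"):
            raise ValidationError(f"kingdom must be 'plant' or 'animal', got {self.kingdom!r}")
        m = self.matrix
        if len(m) < 1:
            raise ValidationError("community must cover at least one site")
        if m.columns.duplicated().any():
            raise ValidationError("duplicate species ids within taxon")
        if m.shape[1]:
            arr = m.to_numpy()
            flat = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(flat)):
                raise ValidationError("non-finite abundance values")
            if np.any(flat < 0) or np.any(flat != np.round(flat)):
                bad = np.argwhere((flat < 0) | (flat != np.round(flat)))[0]
                raise ValidationError(
                    f"counts must be non-negative integers; offending cell "
                    f"row={m.index[bad[0]]!r} column={m.columns[bad[1]]!r}"
                )
            self.matrix = m.astype(np.int64)

    @property
    def site_ids(self) -> list:
        return list(self.matrix.index)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_species(self) -> int:
        return self.matrix.shape[1]

    @property
    def counts(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=np.int64)

    def total_individuals(self) -> int:
        return int(self.counts.sum())

    def check_alignment(self, sites: SiteTable) -> None:
        if list(self.matrix.index) != sites.site_ids:
            raise ValidationError(
                f"community {self.taxon_name!r} site ids do not match the site table"
            )


@dataclass
class TaxonSpec:
    """Generative recipe for one synthetic taxonomic group.

    ``driver_coefficients`` maps covariate name to its effect size on log
    expected per-site richness (per s.d. of the covariate).
    ``range_width_mean`` is the mean elevational range width (m);
    ``range_midpoint`` selects how species midpoints are placed:
    ``("uniform",)`` over the gradient or ``("gaussian", optimum_m, sd_m)``
    around a taxon optimum.  ``detection_rate`` is the expected number of
    individuals recorded per present species (≥ 1 for sampled taxa).
    ``occupancy`` sets baseline expected site richness as a fraction of the
    pool; with ``flatten_range_profile`` the range-coverage profile is
    divided out so expected richness follows the linear predictor exactly.
    """

    taxon_name: str
    kingdom: str = "animal"
    n_species_pool: int = 100
    driver_coefficients: Mapping[str, float] = field(default_factory=dict)
    range_width_mean: float = 1500.0
    range_midpoint: tuple = ("uniform",)
    detection_rate: float = 5.0
    occupancy: float = 0.3
    flatten_range_profile: bool = True
    is_census: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_species_pool < 0:
            raise ValidationError("n_species_pool must be >= 0")
        if self.detection_rate < 0:
            raise ValidationError("detection_rate must be >= 0")
        if self.range_width_mean <= 0:
            raise ValidationError("range_width_mean must be > 0")
        if not 0 < self.occupancy <= 1:
            raise ValidationError("occupancy must be in (0, 1]")
        if self.range_midpoint[0] not in ("uniform", "gaussian"):
            raise ValidationError(f"unknown midpoint distribution {self.range_midpoint[0]!r}")
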
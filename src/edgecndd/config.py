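"""Configuration objects for the sampling design and the simulated community.

The design mirrors a nested field layout used to study edge effects on
seedling recruitment: locations along forest edges, each carrying sampling
stations in edge-distance bands (E0 = 0-5 m, E1 = 20-30 m, E2 = 50-60 m,
E3 = 90-100 m).  Every station holds two 1-m2 seed traps and five 1-m2
seedling plots, one plot per exclusion treatment (untreated control,
water-sprayed control, fungicide, insecticide, both pesticides).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

EDGE_CATEGORIES = ("E0", "E1", "E2", "E3")
NEAR_EDGE_CATEGORIES = ("E0", "E1", "E2")
DEFAULT_TREATMENTS = ("control", "water", "fungicide", "insecticide", "both")


@dataclass
class DesignConfig:
    """Layout of locations, stations, traps and plots.

    Defaults reproduce the reference design: 15 locations x 3 stations in
    each of E0/E1/E2 (45 per band) plus 15 E3 stations shared by 5 of the
    locations, 2 traps and 5 plots per station.
    """

    n_locations: int = 15
    replicates_per_distance: int = 3
    n_e3_stations: int = 15
    n_e3_locations: int = 5
    traps_per_station: int = 2
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    near_edge_categories: tuple[str, ...] = NEAR_EDGE_CATEGORIES
    n_stations_override: int | None = None

    @property
    def plots_per_station(self) -> int:
        # exactly one plot per treatment per station
        return len(self.treatments)

    def __post_init__(self) -> None:
        for name in ("n_locations", "replicates_per_distance", "traps_per_station"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_e3_stations < 0:
            raise ValueError("n_e3_stations must be >= 0")
        if self.n_e3_stations > self.n_locations * self.replicates_per_distance:
            raise ValueError(
                "n_e3_stations exceeds n_locations x replicates_per_distance "
                f"({self.n_e3_stations} > {self.n_locations * self.replicates_per_distance})"
            )
        if self.n_e3_stations > 0 and not (1 <= self.n_e3_locations <= self.n_locations):
            raise ValueError("n_e3_locations must be in [1, n_locations]")
        if len(set(self.treatments)) != len(self.treatments) or not self.treatments:
            raise ValueError("treatments must be a non-empty set of distinct labels")
        self.treatments = tuple(self.treatments)
        self.near_edge_categories = tuple(self.near_edge_categories)

    @property
    def edge_categories(self) -> tuple[str, ...]:
        cats = list(self.near_edge_categories)
        if self.n_e3_stations > 0:
            cats.append("E3")
        return tuple(cats)

    def n_stations(self) -> int:
        n = (
            self.n_locations
            * self.replicates_per_distance
            * len(self.near_edge_categories)
            + self.n_e3_stations
        )
        if self.n_stations_override is not None:
            n = min(n, self.n_stations_override)
        return n

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CommunityParams:
    """Ground-truth parameters of the simulated plant community.

    The community follows a ranked species-abundance law; each station draws
    a latent per-m2 seed density per species log-normally around the species
    mean, traps count that density with Poisson noise, and recruitment into
    plots follows the power law ``R = a * S**b`` with negative-binomial noise
    (``b = 1`` means density-independent transition; ``b < 1`` means
    conspecific negative density dependence).
    """

    n_species: int = 40
    abundance_distribution: str = "log_series"
    abundance_shape: float = 0.95
    total_seed_density: float = 200.0
    seed_density_lognormal_sd: float = 0.8
    trap_noise_model: str = "poisson"
    a: float | Sequence[float] = 0.25
    b_matrix: object = 1.0  # scalar, or DataFrame edge x treatment
    a_treatment_multiplier: dict[str, float] | None = None
    species_slope_sd: float = 0.1
    nb_dispersion: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.abundance_distribution not in ("log_series", "lognormal"):
            raise ValueError(
                f"unknown abundance_distribution {self.abundance_distribution!r}"
            )
        if self.trap_noise_model != "poisson":
            raise ValueError(f"unknown trap_noise_model {self.trap_noise_model!r}")
        if self.total_seed_density < 0:
            raise ValueError("total_seed_density must be >= 0")
        if self.seed_density_lognormal_sd < 0:
            raise ValueError("seed_density_lognormal_sd must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion (phi) must be > 0")
        if self.species_slope_sd < 0:
            raise ValueError("species_slope_sd must be >= 0")
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        if np.any(a <= 0) or np.any(a > 1):
            raise ValueError("a must lie in (0, 1]")

    def species_a(self) -> np.ndarray:
        a = np.asarray(self.a, dtype=float)
        if a.ndim == 0:
            return np.full(self.n_species, float(a))
        if a.shape != (self.n_species,):
            raise ValueError("per-species a must have length n_species")
        return a

    def relative_abundances(self, rng: np.random.Generator) -> np.ndarray:
        """Relative abundance of each species, summing to one.

        ``log_series`` is a deterministic ranked Fisher log-series
        (p_s proportional to theta**s / s); ``lognormal`` draws relative
        abundances from a log-normal with log-SD ``abundance_shape``.
        """
        s = np.arange(1, self.n_species + 1)
        if self.abundance_distribution == "log_series":
            theta = self.abundance_shape
            if not 0 < theta < 1:
                raise ValueError("log_series shape theta must be in (0, 1)")
            p = theta**s / s
        else:
            p = np.sort(rng.lognormal(0.0, self.abundance_shape, self.n_species))[::-1]
        p = p / p.sum()
        if not np.isclose(p.sum(), 1.0):
            raise AssertionError("relative abundances must sum to 1")
        return p

    def b_table(self, edge_categories: Sequence[str], treatments: Sequence[str]) -> pd.DataFrame:
        """Cell-level density-dependence slope b as edge x treatment table."""
        if np.isscalar(self.b_matrix):
            return pd.DataFrame(
                float(self.b_matrix),
                index=list(edge_categories),
                columns=list(treatments),
            )
        bm = pd.DataFrame(self.b_matrix).astype(float)
        missing_rows = set(edge_categories) - set(bm.index)
        missing_cols = set(treatments) - set(bm.columns)
        if missing_rows or missing_cols:
            raise ValueError(
                f"b_matrix missing edge rows {sorted(missing_rows)} "
                f"or treatment columns {sorted(missing_cols)}"
            )
        bm = bm.loc[list(edge_categories), list(treatments)]
        if not np.all(np.isfinite(bm.to_numpy())):
            raise ValueError("b_matrix entries must be finite")
        return bm

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(self.b_matrix, pd.DataFrame):
            d["b_matrix"] = {
                "index": list(self.b_matrix.index),
                "columns": list(self.b_matrix.columns),
                "values": self.b_matrix.to_numpy().tolist(),
            }
        a = np.asarray(self.a, dtype=float)
        d["a"] = float(a) if a.ndim == 0 else a.tolist()
        return d


def b_matrix_from_dict(d: dict) -> pd.DataFrame:
    return pd.DataFrame(d["values"], index=d["index"], columns=d["columns"])
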
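"""Synthetic data generator for the edge-effect enemy-exclusion design.

Generates station/trap/plot skeletons, latent per-station seed densities,
Poisson trap counts, and negative-binomial seedling-recruit counts under the
power-law transition ``R = a * S**b``, with the full ground truth retained so
recovery of every parameter can be tested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CommunityParams, DesignConfig, b_matrix_from_dict

__all__ = [
    "Design",
    "GroundTruth",
    "generate_design",
    "simulate_seed_rain",
    "simulate_recruitment",
    "simulate_dataset",
    "write_dataset",
    "e3_control_cndd_scenario",
]


@dataclass
class Design:
    """Station table plus trap and plot skeleton tables."""

    stations: pd.DataFrame  # station_id, location_id, edge_category
    traps: pd.DataFrame  # station_id, trap_id
    plots: pd.DataFrame  # plot_id, station_id, treatment
    config: DesignConfig


@dataclass
class GroundTruth:
    """Everything the generator knew: parameters, latent states, realized slopes."""

    params: CommunityParams
    species: list[str]
    rel_abundance: np.ndarray  # (S,) sums to 1
    lam: pd.DataFrame  # stations x species latent seed density per m2
    b_cell: pd.DataFrame  # edge x treatment slopes
    u_species: np.ndarray  # (S,) per-species slope deviations
    a_species: np.ndarray  # (S,)

    def b_realized(self, edge: str, treatment: str) -> np.ndarray:
        """Per-species slope in one edge x treatment cell."""
        return self.b_cell.loc[edge, treatment] + self.u_species

    def to_json(self) -> str:
        payload = {
            "params": self.params.to_dict(),
            "species": self.species,
            "rel_abundance": self.rel_abundance.tolist(),
            "lam": {
                "index": list(self.lam.index),
                "columns": list(self.lam.columns),
                "values": self.lam.to_numpy().tolist(),
            },
            "b_cell": {
                "index": list(self.b_cell.index),
                "columns": list(self.b_cell.columns),
                "values": self.b_cell.to_numpy().tolist(),
            },
            "u_species": self.u_species.tolist(),
            "a_species": self.a_species.tolist(),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        pd_params = dict(d["params"])
        if isinstance(pd_params.get("b_matrix"), dict):
            pd_params["b_matrix"] = b_matrix_from_dict(pd_params["b_matrix"])
        params = CommunityParams(**pd_params)
        return cls(
            params=params,
            species=d["species"],
            rel_abundance=np.asarray(d["rel_abundance"]),
            lam=pd.DataFrame(
                d["lam"]["values"], index=d["lam"]["index"], columns=d["lam"]["columns"]
            ),
            b_cell=pd.DataFrame(
                d["b_cell"]["values"],
                index=d["b_cell"]["index"],
                columns=d["b_cell"]["columns"],
            ),
            u_species=np.asarray(d["u_species"]),
            a_species=np.asarray(d["a_species"]),
        )


def generate_design(config: DesignConfig, rng_seed: int = 0) -> Design:
    """Lay out stations, traps and plots.

    One station per (location, edge band, replicate); E3 stations are spread
    round-robin over the first ``n_e3_locations`` locations.  Each station
    receives ``traps_per_station`` traps and one plot per treatment, with the
    treatment order shuffled per station under ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    for li in range(config.n_locations):
        loc = f"L{li + 1:02d}"
        for cat in config.near_edge_categories:
            for rep in range(1, config.replicates_per_distance + 1):
                rows.append((f"{loc}-{cat}-{rep}", loc, cat))
    e3_locs = [f"L{li + 1:02d}" for li in range(config.n_e3_locations)]
    e3_counts: dict[str, int] = {loc: 0 for loc in e3_locs}
    for k in range(config.n_e3_stations):
        loc = e3_locs[k % len(e3_locs)]
        e3_counts[loc] += 1
        rows.append((f"{loc}-E3-{e3_counts[loc]}", loc, "E3"))
    stations = pd.DataFrame(rows, columns=["station_id", "location_id", "edge_category"])

    if config.n_stations_override is not None:
        n_keep = config.n_stations_override
        if n_keep > len(stations):
            raise ValueError(
                f"n_stations_override={n_keep} exceeds the {len(stations)} "
                "stations the design produces"
            )
        keep = np.sort(rng.choice(len(stations), size=n_keep, replace=False))
        stations = stations.iloc[keep].reset_index(drop=True)

    traps = pd.DataFrame(
        [
            (sid, trap)
            for sid in stations["station_id"]
            for trap in range(1, config.traps_per_station + 1)
        ],
        columns=["station_id", "trap_id"],
    )

    plot_rows = []
    for sid in stations["station_id"]:
        order = rng.permutation(len(config.treatments))
        for pos, ti in enumerate(order, start=1):
            plot_rows.append((f"{sid}-P{pos}", sid, config.treatments[ti]))
    plots = pd.DataFrame(plot_rows, columns=["plot_id", "station_id", "treatment"])
    return Design(stations=stations, traps=traps, plots=plots, config=config)


def simulate_seed_rain(
    design: Design, params: CommunityParams
) -> tuple[GroundTruth, pd.DataFrame]:
    """Draw latent seed densities and Poisson trap counts.

    The latent density of species s at station j is log-normal around the
    species mean density (mean-preserving: the log-normal's expectation equals
    ``total_seed_density * p_s``), with log-SD ``seed_density_lognormal_sd``.
    Each trap independently counts Poisson(lambda_js) seeds.
    """
    rng = np.random.default_rng(params.rng_seed)
    species = [f"sp{k + 1:03d}" for k in range(params.n_species)]
    p = params.relative_abundances(rng)
    mean_density = params.total_seed_density * p

    sids = list(design.stations["station_id"])
    J, S = len(sids), params.n_species
    sd = params.seed_density_lognormal_sd
    with np.errstate(divide="ignore"):
        log_mean = np.log(mean_density)
    mu = log_mean - 0.5 * sd**2  # lognormal mean == mean_density
    log_lam = mu[None, :] + sd * rng.standard_normal((J, S))
    lam = np.where(mean_density[None, :] > 0, np.exp(log_lam), 0.0)
    lam_df = pd.DataFrame(lam, index=sids, columns=species)

    n_traps = design.config.traps_per_station
    counts = rng.poisson(np.repeat(lam, n_traps, axis=0))  # (J*n_traps, S)
    trap_rows = []
    for row, (sid, trap_id) in zip(
        counts, ((sid, t) for sid in sids for t in range(1, n_traps + 1))
    ):
        nz = np.nonzero(row)[0]
        trap_rows.extend((sid, trap_id, species[k], int(row[k])) for k in nz)
    traps = pd.DataFrame(trap_rows, columns=["station_id", "trap_id", "species_id", "count"])

    b_cell = params.b_table(design.config.edge_categories, design.config.treatments)
    u = params.species_slope_sd * rng.standard_normal(S)
    truth = GroundTruth(
        params=params,
        species=species,
        rel_abundance=p,
        lam=lam_df,
        b_cell=b_cell,
        u_species=u,
        a_species=params.species_a(),
    )
    return truth, traps


def simulate_recruitment(truth: GroundTruth, design: Design) -> pd.DataFrame:
    """Draw seedling recruit counts per plot x species.

    Mean recruits for species s in a plot of treatment t at station j is
    ``a_s * lambda_js ** b(s, edge_j, t)`` (zero when lambda is zero), with
    negative-binomial noise of size ``nb_dispersion``; all plots of a station
    share the station's latent density.  A second RNG stream derived from the
    community seed keeps seed rain and recruitment reproducible independently.
    """
    params = truth.params
    rng = np.random.default_rng(np.random.SeedSequence(params.rng_seed).spawn(2)[1])
    edge_of = dict(
        zip(design.stations["station_id"], design.stations["edge_category"])
    )
    a = truth.a_species.copy()
    phi = params.nb_dispersion
    lam = truth.lam
    mult = params.a_treatment_multiplier or {}

    rows = []
    for plot_id, sid, treatment in design.plots.itertuples(index=False):
        edge = edge_of[sid]
        b = truth.b_realized(edge, treatment)
        lam_j = lam.loc[sid].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            mean = a * mult.get(treatment, 1.0) * lam_j**b
        mean = np.where(lam_j > 0, mean, 0.0)
        r = np.where(mean > 0, rng.negative_binomial(phi, phi / (phi + mean)), 0)
        nz = np.nonzero(r)[0]
        rows.extend(
            (plot_id, sid, treatment, truth.species[k], int(r[k])) for k in nz
        )
    return pd.DataFrame(
        rows, columns=["plot_id", "station_id", "treatment", "species_id", "recruits"]
    )


def simulate_dataset(
    design_config: DesignConfig,
    params: CommunityParams,
    design_seed: int | None = None,
) -> tuple[Design, GroundTruth, pd.DataFrame, pd.DataFrame]:
    """Full simulation: design, seed rain, recruitment.

    Returns (design, truth, traps, plots) with plot metadata and recruit
    counts merged into the plots table convention used on disk.
    """
    if design_seed is None:
        design_seed = params.rng_seed
    design = generate_design(design_config, rng_seed=design_seed)
    truth, traps = simulate_seed_rain(design, params)
    recruits = simulate_recruitment(truth, design)
    return design, truth, traps, recruits


def write_dataset(
    design: Design,
    traps: pd.DataFrame,
    plots: pd.DataFrame,
    truth: GroundTruth | None,
    directory: str | Path,
    overwrite: bool = False,
) -> None:
    """Write stations.csv, traps.csv, plots.csv (metadata + counts) and truth.json.

    ``plots.csv`` carries one row per plot x species with recruits > 0 plus
    one sentinel row (empty species, recruits empty) per plot so plot
    metadata survives even for plots with no recruits.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    targets = ["stations.csv", "traps.csv", "plots.csv", "truth.json"]
    if not overwrite:
        clashes = [t for t in targets if (directory / t).exists()]
        if clashes:
            raise FileExistsError(
                f"refusing to overwrite {clashes} in {directory}; pass overwrite=True"
            )
    design.stations.to_csv(directory / "stations.csv", index=False)
    traps.to_csv(directory / "traps.csv", index=False)

    meta = design.plots.copy()
    meta["species_id"] = ""
    meta["recruits"] = pd.NA
    full = pd.concat([meta, plots], ignore_index=True)
    full = full[["plot_id", "station_id", "treatment", "species_id", "recruits"]]
    full.to_csv(directory / "plots.csv", index=False)
    if truth is not None:
        (directory / "truth.json").write_text(truth.to_json())


def e3_control_cndd_scenario(
    b_baseline: float = 0.9, b_e3_control: float = 0.4, **overrides
) -> CommunityParams:
    """Community in which strong CNDD operates only in untreated E3 plots.

    Pesticide plots (and all plots nearer the edge) keep the mild baseline
    slope; the control and water plots at E3 get the strong-CNDD slope, the
    configuration under which enemy exclusion should lower recruit diversity
    only in the interior.  Slope magnitudes follow typical community-level
    estimates for the seed-to-seedling transition (b roughly 0.4-1).
    """
    from .config import DEFAULT_TREATMENTS, EDGE_CATEGORIES

    b = pd.DataFrame(
        b_baseline, index=list(EDGE_CATEGORIES), columns=list(DEFAULT_TREATMENTS)
    )
    b.loc["E3", "control"] = b_e3_control
    b.loc["E3", "water"] = b_e3_control
    return CommunityParams(b_matrix=b, **overrides)
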
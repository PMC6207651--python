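"""Readers and schema validation for the station/trap/plot CSV tables.

Schemas (UTF-8, comma-delimited, header row, empty field = missing):

* ``stations.csv`` — station_id, location_id, edge_category
* ``traps.csv`` — station_id, trap_id, species_id, count (sparse: only
  positive counts are stored)
* ``plots.csv`` — plot_id, station_id, treatment, species_id, recruits
  (sparse counts plus one sentinel row with empty species per plot, so plot
  metadata survives for plots with no recruits)
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .config import DEFAULT_TREATMENTS, EDGE_CATEGORIES

log = logging.getLogger("edgecndd")

__all__ = ["SchemaError", "read_tables"]


class SchemaError(ValueError):
    """A table violated its documented schema."""


def _require_columns(df: pd.DataFrame, cols: list[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{fname}: missing columns {missing}")


def _normalize_treatments(plots: pd.DataFrame, fname: str,
                          allowed: tuple[str, ...]) -> pd.DataFrame:
    lower = plots["treatment"].astype(str).str.strip().str.lower()
    changed = (lower != plots["treatment"]).sum()
    if changed:
        log.warning("%s: normalized case/whitespace of %d treatment labels", fname, changed)
    bad = sorted(set(lower) - set(allowed))
    if bad:
        first_bad = lower[~lower.isin(allowed)].index[0]
        raise SchemaError(
            f"{fname}: row {first_bad + 2}: treatment label(s) {bad} not in {allowed}"
        )
    plots = plots.copy()
    plots["treatment"] = lower
    return plots


def read_tables(
    directory: str | Path,
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS,
    edge_categories: tuple[str, ...] = EDGE_CATEGORIES,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load and validate stations.csv, traps.csv, plots.csv.

    Enforces referential integrity (every trap/plot references an existing
    station), non-negative counts, known edge categories, and normalizes
    treatment label case with a warning.  Raises :class:`SchemaError` naming
    the file, row and failed rule.
    """
    directory = Path(directory)
    paths = {name: directory / f"{name}.csv" for name in ("stations", "traps", "plots")}
    for name, p in paths.items():
        if not p.exists():
            raise SchemaError(f"{p}: file not found")

    stations = pd.read_csv(paths["stations"], dtype={"station_id": str, "location_id": str})
    _require_columns(stations, ["station_id", "location_id", "edge_category"], "stations.csv")
    if stations["station_id"].duplicated().any():
        dup = stations.loc[stations["station_id"].duplicated(), "station_id"].iloc[0]
        raise SchemaError(f"stations.csv: duplicated station_id {dup!r}")
    bad_edges = sorted(set(stations["edge_category"]) - set(edge_categories))
    if bad_edges:
        raise SchemaError(f"stations.csv: unknown edge categories {bad_edges}")
    known = set(stations["station_id"])

    traps = pd.read_csv(paths["traps"], dtype={"station_id": str, "species_id": str})
    _require_columns(traps, ["station_id", "trap_id", "species_id", "count"], "traps.csv")
    unknown = traps.loc[~traps["station_id"].isin(known)]
    if len(unknown):
        i = unknown.index[0]
        raise SchemaError(
            f"traps.csv: row {i + 2}: station_id {unknown['station_id'].iloc[0]!r} "
            "not present in stations.csv"
        )
    if (traps["count"] < 0).any():
        i = traps.index[traps["count"] < 0][0]
        raise SchemaError(f"traps.csv: row {i + 2}: negative count")

    plots = pd.read_csv(
        paths["plots"],
        dtype={"plot_id": str, "station_id": str, "species_id": str},
        keep_default_na=True,
    )
    _require_columns(
        plots, ["plot_id", "station_id", "treatment", "species_id", "recruits"], "plots.csv"
    )
    plots["species_id"] = plots["species_id"].fillna("")
    unknown = plots.loc[~plots["station_id"].isin(known)]
    if len(unknown):
        i = unknown.index[0]
        raise SchemaError(
            f"plots.csv: row {i + 2}: station_id {unknown['station_id'].iloc[0]!r} "
            "not present in stations.csv"
        )
    plots = _normalize_treatments(plots, "plots.csv", treatments)
    counted = plots[plots["species_id"] != ""]
    if counted["recruits"].isna().any():
        i = counted.index[counted["recruits"].isna()][0]
        raise SchemaError(f"plots.csv: row {i + 2}: species row with missing recruits")
    if (counted["recruits"] < 0).any():
        i = counted.index[counted["recruits"] < 0][0]
        raise SchemaError(f"plots.csv: row {i + 2}: negative recruits")

    log.info(
        "loaded %d stations, %d trap count rows, %d plots",
        len(stations), len(traps), plots["plot_id"].nunique(),
    )
    return stations, traps, plots
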
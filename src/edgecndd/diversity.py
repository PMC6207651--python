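"""Hill-number diversity indices and per-unit diversity tables.

Three indices in effective-species units: rarefied richness (expected species
in a fixed-size subsample, hypergeometric), inverse Simpson (Hill order 2)
and exponentiated Shannon (Hill order 1).  Seedling assemblages are scored
per plot; seed assemblages per station with the two traps pooled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "inverse_simpson",
    "exp_shannon",
    "rarefied_richness",
    "diversity_table",
    "pool_controls",
]


def _proportions(counts) -> np.ndarray | None:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("abundance vector must be one-dimensional")
    if np.any(c < 0) or not np.all(np.isfinite(c)):
        raise ValueError("counts must be finite and non-negative")
    total = c.sum()
    if total == 0:
        return None
    return c[c > 0] / total


def inverse_simpson(counts) -> float:
    """Hill number of order 2, 1 / sum(p_i^2); NaN for an empty assemblage."""
    p = _proportions(counts)
    if p is None:
        return float("nan")
    return 1.0 / float(np.sum(p**2))


def exp_shannon(counts) -> float:
    """Hill number of order 1, exp(-sum(p_i ln p_i)); NaN for an empty assemblage."""
    p = _proportions(counts)
    if p is None:
        return float("nan")
    return float(np.exp(-np.sum(p * np.log(p))))


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness(counts, n: int) -> float:
    """Expected species count in a subsample of ``n`` individuals.

    Hypergeometric (sampling without replacement):
    ``sum_i [1 - C(N - N_i, n) / C(N, n)]``.  Assemblages with fewer than
    ``n`` individuals return NaN rather than extrapolating.
    """
    if n < 1:
        raise ValueError("subsample size n must be >= 1")
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    N = c.sum()
    if N == 0 or N < n:
        return float("nan")
    rem = N - c
    # C(N - N_i, n) = 0 whenever N - N_i < n
    with np.errstate(invalid="ignore"):
        logp = _log_comb(rem, n) - _log_comb(np.array(N), n)
    p_absent = np.where(rem >= n, np.exp(logp), 0.0)
    return float(np.sum(1.0 - p_absent))


_INDEX_FUNCS = {
    "inverse_simpson": lambda v, n: inverse_simpson(v),
    "exp_shannon": lambda v, n: exp_shannon(v),
    "rarefied_richness": lambda v, n: rarefied_richness(v, n),
}
INDEX_NAMES = tuple(_INDEX_FUNCS)


def _unit_indices(counts: np.ndarray, rarefy_n: int) -> dict[str, float]:
    return {name: f(counts, rarefy_n) for name, f in _INDEX_FUNCS.items()}


def diversity_table(
    traps: pd.DataFrame,
    plots: pd.DataFrame,
    stations: pd.DataFrame,
    rarefy_n_seeds: int = 5,
    rarefy_n_seedlings: int = 2,
    indices: tuple[str, ...] = INDEX_NAMES,
) -> pd.DataFrame:
    """Index values for every seedling plot and every station's seed pool.

    Returns long format: unit_id, unit_kind ('seed'|'seedling'), station_id,
    treatment (seed rows empty), edge_category, index, value.  Units with no
    individuals (or too few to rarefy) get NaN.
    """
    edge_of = dict(zip(stations["station_id"], stations["edge_category"]))
    rows = []

    seed_counts = (
        traps.groupby(["station_id", "species_id"], sort=False)["count"].sum()
        if len(traps)
        else pd.Series(dtype=int)
    )
    for sid in stations["station_id"]:
        v = (
            seed_counts.loc[sid].to_numpy()
            if len(traps) and sid in seed_counts.index.get_level_values(0)
            else np.zeros(0)
        )
        vals = _unit_indices(v, rarefy_n_seeds)
        for name in indices:
            rows.append((sid, "seed", sid, "", edge_of[sid], name, vals[name]))

    plot_meta = plots[["plot_id", "station_id", "treatment"]].drop_duplicates("plot_id")
    counted = plots.dropna(subset=["recruits"]) if "recruits" in plots else plots
    counted = counted[counted.get("species_id", "") != ""]
    by_plot = counted.groupby("plot_id", sort=False)
    for plot_id, sid, treatment in plot_meta.itertuples(index=False):
        if plot_id in by_plot.groups:
            v = by_plot.get_group(plot_id)["recruits"].to_numpy(dtype=float)
        else:
            v = np.zeros(0)
        vals = _unit_indices(v, rarefy_n_seedlings)
        for name in indices:
            rows.append(
                (plot_id, "seedling", sid, treatment, edge_of[sid], name, vals[name])
            )
    return pd.DataFrame(
        rows,
        columns=[
            "unit_id",
            "unit_kind",
            "station_id",
            "treatment",
            "edge_category",
            "index",
            "value",
        ],
    )


def pool_controls(
    dtable: pd.DataFrame,
    control_labels: tuple[str, str] = ("control", "water"),
    pooled_label: str = "Control",
) -> pd.DataFrame:
    """Collapse the untreated and water-sprayed plots into one Control value.

    Per station and index, Control diversity is the arithmetic mean of the
    two plots' values; if one of the two is missing the available value is
    used and the row is flagged.  Other treatments pass through unchanged.
    Seed rows pass through unchanged.
    """
    seed_rows = dtable[dtable["unit_kind"] == "seed"].copy()
    seedling = dtable[dtable["unit_kind"] == "seedling"].copy()
    is_ctrl = seedling["treatment"].isin(control_labels)
    others = seedling[~is_ctrl].copy()
    others["pooled_flag"] = False

    ctrl = seedling[is_ctrl]
    pooled_rows = []
    for (sid, index_name), grp in ctrl.groupby(["station_id", "index"], sort=False):
        vals = grp["value"].dropna()
        flag = len(grp) < 2 or grp["value"].isna().any()
        value = float(vals.mean()) if len(vals) else float("nan")
        ref = grp.iloc[0]
        pooled_rows.append(
            {
                "unit_id": f"{sid}-{pooled_label}",
                "unit_kind": "seedling",
                "station_id": sid,
                "treatment": pooled_label,
                "edge_category": ref["edge_category"],
                "index": index_name,
                "value": value,
                "pooled_flag": flag,
            }
        )
    seed_rows["pooled_flag"] = False
    return pd.concat(
        [seed_rows, pd.DataFrame(pooled_rows), others], ignore_index=True
    )
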
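"""Mixed-effects contrasts of recruit diversity across edge x treatment cells.

Recruit diversity per plot is modelled as Gaussian with fixed effects for the
edge-distance x treatment interaction, the station's seed diversity as an
additive covariate, and a station-level random intercept.  Pairwise cell
differences are tested with Wald z statistics; the familywise correction for
the within-edge treatment comparisons is configurable (none or a Tukey-style
studentized-range adjustment) and significant groupings are reported as
compact letter displays.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["DiversityModelFit", "fit_diversity_model", "fit_light_model"]


@dataclass
class DiversityModelFit:
    index: str
    formula: str
    cell_means: pd.DataFrame  # cell labels, estimate, se
    contrasts: pd.DataFrame  # cell_a, cell_b, estimate, se, z, p, p_adj, significant
    letters: dict  # group -> {cell: letters}
    seed_div_coef: float
    seed_div_se: float
    station_intercept_var: float
    n_obs: int
    n_dropped: int
    used_fallback: bool
    converged: bool
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "formula": self.formula,
            "cell_means": self.cell_means.to_dict(orient="records"),
            "contrasts": self.contrasts.to_dict(orient="records"),
            "letters": self.letters,
            "seed_div_coef": self.seed_div_coef,
            "seed_div_se": self.seed_div_se,
            "station_intercept_var": self.station_intercept_var,
            "n_obs": self.n_obs,
            "n_dropped": self.n_dropped,
            "used_fallback": self.used_fallback,
            "converged": self.converged,
        }


def attach_seed_diversity(dtable: pd.DataFrame, index: str) -> pd.DataFrame:
    """One row per seedling unit of ``index`` with its station's seed diversity."""
    sdl = dtable[(dtable["unit_kind"] == "seedling") & (dtable["index"] == index)]
    seed = dtable[(dtable["unit_kind"] == "seed") & (dtable["index"] == index)]
    seed_map = dict(zip(seed["station_id"], seed["value"]))
    out = sdl.copy()
    out["seed_div"] = out["station_id"].map(seed_map)
    return out


def _fit_gaussian_mixed(df: pd.DataFrame, formula: str):
    """MixedLM with station random intercept; OLS fallback on singular fits."""
    used_fallback = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups=df["station_id"])
            res = None
            for method in ("lbfgs", "bfgs", "powell"):
                try:
                    cand = model.fit(reml=True, method=method)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if cand.converged and np.all(np.isfinite(cand.bse_fe)):
                    res = cand
                    break
            if res is None:
                raise np.linalg.LinAlgError("singular mixed fit")
            k_fe = len(res.fe_params)
            beta = np.asarray(res.fe_params)
            cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
            re_var = float(res.cov_re.iloc[0, 0])
            design_info = model.data.design_info
        except (np.linalg.LinAlgError, ValueError):
            warnings.warn(
                "random-intercept fit singular; falling back to fixed-intercept OLS",
                stacklevel=3,
            )
            used_fallback = True
            ols = smf.ols(formula, df).fit()
            beta = np.asarray(ols.params)
            cov = np.asarray(ols.cov_params())
            re_var = 0.0
            design_info = ols.model.data.design_info
            converged = True
    return beta, cov, re_var, design_info, used_fallback, converged


def _design_row(design_info, row: dict) -> np.ndarray:
    (mat,) = patsy.build_design_matrices([design_info], pd.DataFrame([row]))
    return np.asarray(mat)[0]


def _wald(L: np.ndarray, beta: np.ndarray, cov: np.ndarray) -> tuple[float, float, float]:
    est = float(L @ beta)
    se = float(np.sqrt(L @ cov @ L))
    z = est / se if se > 0 else 0.0
    return est, se, z


def _tukey_p(z: float, k: int, df: float) -> float:
    """Studentized-range tail probability for a pairwise z among k means."""
    if k < 2:
        return float(stats.norm.sf(abs(z)) * 2)
    return float(stats.studentized_range.sf(abs(z) * np.sqrt(2.0), k, max(df, 10.0)))


def compact_letters(cells: list[str], different: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: cells sharing a letter are not significantly different.

    Letters are assigned to maximal cliques of the 'not different' graph,
    ordered by first member.
    """
    not_diff = {
        frozenset(p)
        for p in itertools.combinations(cells, 2)
        if tuple(sorted(p)) not in different and tuple(sorted(p))[::-1] not in different
    }

    def is_clique(sub: tuple[str, ...]) -> bool:
        return all(frozenset(p) in not_diff for p in itertools.combinations(sub, 2))

    cliques: list[tuple[str, ...]] = []
    for r in range(len(cells), 0, -1):
        for sub in itertools.combinations(cells, r):
            if is_clique(sub) and not any(set(sub) <= set(c) for c in cliques):
                cliques.append(sub)
    letters = {c: "" for c in cells}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for c in clique:
            letters[c] += letter
    return letters


def _contrast_frame(rows: list[dict], k_family: int, df_resid: float, correction: str) -> pd.DataFrame:
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if correction == "tukey":
        out["p_adj"] = [
            _tukey_p(z, k, df_resid) for z, k in zip(out["z"], out["k_family"])
        ]
    elif correction == "none":
        out["p_adj"] = out["p"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    out["significant"] = out["p_adj"] < 0.05
    return out.drop(columns=["k_family"])


def fit_diversity_model(
    dtable: pd.DataFrame,
    index: str = "inverse_simpson",
    correction: str = "tukey",
) -> DiversityModelFit:
    """Fit recruit diversity ~ edge x treatment + seed diversity, station intercepts.

    ``dtable`` is the long diversity table (after control pooling) containing
    both seedling and seed rows for ``index``.  Plots with undefined diversity
    (zero recruits, or too few individuals to rarefy) are dropped and counted.
    """
    df = attach_seed_diversity(dtable, index)
    n_total = len(df)
    df = df.dropna(subset=["value", "seed_div"]).copy()
    n_dropped = n_total - len(df)
    edges = sorted(df["edge_category"].unique())
    treatments = sorted(df["treatment"].unique())
    formula = "value ~ C(edge_category) * C(treatment) + seed_div"
    if df["value"].nunique() == 1:
        # degenerate: constant response, all contrasts identically zero
        cells = [
            {"edge_category": e, "treatment": t, "estimate": float(df["value"].iloc[0]), "se": 0.0}
            for e in edges
            for t in treatments
        ]
        rows = []
        for e in edges:
            for t1, t2 in itertools.combinations(treatments, 2):
                rows.append(
                    dict(group=e, cell_a=f"{e}:{t1}", cell_b=f"{e}:{t2}", estimate=0.0,
                         se=0.0, z=0.0, p=1.0, k_family=len(treatments))
                )
        contrasts = _contrast_frame(rows, len(treatments), len(df), correction)
        letters = {e: {t: "a" for t in treatments} for e in edges}
        return DiversityModelFit(
            index, formula, pd.DataFrame(cells), contrasts, letters,
            0.0, 0.0, 0.0, len(df), n_dropped, False, True,
        )

    beta, cov, re_var, design_info, used_fallback, converged = _fit_gaussian_mixed(df, formula)
    mean_sd = float(df["seed_div"].mean())

    cell_rows, xrow = [], {}
    for e in edges:
        for t in treatments:
            x = _design_row(
                design_info, {"edge_category": e, "treatment": t, "seed_div": mean_sd}
            )
            xrow[(e, t)] = x
            est, se, _ = _wald(x, beta, cov)
            cell_rows.append(
                {"edge_category": e, "treatment": t, "estimate": est, "se": se}
            )

    df_resid = float(len(df) - len(beta))
    rows = []
    for e in edges:  # treatment comparisons within each edge band
        for t1, t2 in itertools.combinations(treatments, 2):
            L = xrow[(e, t1)] - xrow[(e, t2)]
            est, se, z = _wald(L, beta, cov)
            rows.append(
                dict(group=e, cell_a=f"{e}:{t1}", cell_b=f"{e}:{t2}", estimate=est,
                     se=se, z=z, p=2 * stats.norm.sf(abs(z)), k_family=len(treatments))
            )
    for t in treatments:  # edge comparisons within each treatment
        for e1, e2 in itertools.combinations(edges, 2):
            L = xrow[(e1, t)] - xrow[(e2, t)]
            est, se, z = _wald(L, beta, cov)
            rows.append(
                dict(group=f"treatment:{t}", cell_a=f"{e1}:{t}", cell_b=f"{e2}:{t}",
                     estimate=est, se=se, z=z, p=2 * stats.norm.sf(abs(z)),
                     k_family=len(edges))
            )
    contrasts = _contrast_frame(rows, len(treatments), df_resid, correction)

    letters = {}
    for e in edges:
        sub = contrasts[contrasts["group"] == e]
        different = {
            tuple(sorted((a.split(":", 1)[1], b.split(":", 1)[1])))
            for a, b, sig in zip(sub["cell_a"], sub["cell_b"], sub["significant"])
            if sig
        }
        letters[e] = compact_letters(treatments, different)

    names = design_info.column_names
    i_sd = names.index("seed_div")
    return DiversityModelFit(
        index=index,
        formula=formula,
        cell_means=pd.DataFrame(cell_rows),
        contrasts=contrasts,
        letters=letters,
        seed_div_coef=float(beta[i_sd]),
        seed_div_se=float(np.sqrt(cov[i_sd, i_sd])),
        station_intercept_var=re_var,
        n_obs=len(df),
        n_dropped=n_dropped,
        used_fallback=used_fallback,
        converged=converged,
    )


def fit_light_model(
    dtable: pd.DataFrame,
    light: pd.DataFrame,
    index: str = "inverse_simpson",
    correction: str = "tukey",
) -> DiversityModelFit:
    """Recruit diversity vs canopy light x treatment, station intercepts.

    ``light`` has columns unit_id, light (per-plot canopy openness or
    transmitted radiation).  Rows without a light value are dropped with the
    count recorded; a constant light covariate is reported as inestimable.
    """
    df = attach_seed_diversity(dtable, index)
    df = df.merge(light[["unit_id", "light"]], on="unit_id", how="left")
    n_total = len(df)
    df = df.dropna(subset=["value", "seed_div", "light"]).copy()
    n_dropped = n_total - len(df)
    treatments = sorted(df["treatment"].unique())
    formula = "value ~ light * C(treatment) + seed_div"

    if df["light"].nunique() <= 1:
        empty = pd.DataFrame(
            columns=["group", "cell_a", "cell_b", "estimate", "se", "z", "p", "p_adj", "significant"]
        )
        return DiversityModelFit(
            index, formula, pd.DataFrame(columns=["treatment", "estimate", "se"]),
            empty, {}, float("nan"), float("nan"), 0.0, len(df), n_dropped,
            False, True, extra={"light_coef": float("nan"), "light_se": float("nan"),
                                "light_inestimable": True},
        )

    # warn when light is (nearly) an edge-category stand-in
    if "edge_category" in df and df["edge_category"].nunique() > 1:
        grp = df.groupby("edge_category")["light"]
        if float(grp.std().max()) == 0.0:
            warnings.warn(
                "light is constant within edge categories (collinear with edge); "
                "interaction estimates may be ill-conditioned",
                stacklevel=2,
            )

    beta, cov, re_var, design_info, used_fallback, converged = _fit_gaussian_mixed(df, formula)
    cond = np.linalg.cond(
        patsy.build_design_matrices([design_info], df)[0]
    )
    if cond > 1e8:
        warnings.warn(f"design matrix ill-conditioned (condition number {cond:.2g})",
                      stacklevel=2)

    mean_sd = float(df["seed_div"].mean())
    mean_light = float(df["light"].mean())
    cell_rows, xrow = [], {}
    for t in treatments:
        x = _design_row(
            design_info, {"light": mean_light, "treatment": t, "seed_div": mean_sd}
        )
        xrow[t] = x
        est, se, _ = _wald(x, beta, cov)
        cell_rows.append({"treatment": t, "estimate": est, "se": se})

    df_resid = float(len(df) - len(beta))
    rows = []
    for t1, t2 in itertools.combinations(treatments, 2):
        L = xrow[t1] - xrow[t2]
        est, se, z = _wald(L, beta, cov)
        rows.append(
            dict(group="treatment", cell_a=t1, cell_b=t2, estimate=est, se=se, z=z,
                 p=2 * stats.norm.sf(abs(z)), k_family=len(treatments))
        )
    contrasts = _contrast_frame(rows, len(treatments), df_resid, correction)
    different = {
        tuple(sorted((a, b)))
        for a, b, sig in zip(contrasts["cell_a"], contrasts["cell_b"], contrasts["significant"])
        if sig
    }
    letters = {"all": compact_letters(treatments, different)}

    names = design_info.column_names
    i_sd = names.index("seed_div")
    i_light = names.index("light")
    return DiversityModelFit(
        index=index,
        formula=formula,
        cell_means=pd.DataFrame(cell_rows),
        contrasts=contrasts,
        letters=letters,
        seed_div_coef=float(beta[i_sd]),
        seed_div_se=float(np.sqrt(cov[i_sd, i_sd])),
        station_intercept_var=re_var,
        n_obs=len(df),
        n_dropped=n_dropped,
        used_fallback=used_fallback,
        converged=converged,
        extra={
            "light_coef": float(beta[i_light]),
            "light_se": float(np.sqrt(cov[i_light, i_light])),
            "light_inestimable": False,
        },
    )
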
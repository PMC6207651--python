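"""Adaptive Metropolis-within-Gibbs sampler for the hierarchical CNDD model.

Model (one observation per plot x species):

    R_n ~ NegBin(mean = exp(alpha + a_sp[s_n] + g_st[j_n]
                            + (beta[c_n] + u[s_n]) * z[k_n]),  size = phi)
    N(z_k; mu0_k, sig0_k)              trap evidence for the latent log seed
                                       density of a station x species pair:
                                       the log-normal moment-matched to the
                                       two adjacent trap counts (or z fixed,
                                       for the uncorrected comparison model)
    z_k ~ Normal(nu[s_k], omega)       species-level population of log
                                       densities, hyperparameters estimated
    a_sp ~ N(0, sigma_sp),  g_st ~ N(0, sigma_st),  u ~ N(0, tau)

The population layer makes this a structural errors-in-variables model:
noisy trap evidence is shrunk toward the species' typical density, which is
what removes the attenuation of the slope.  Without it (evidence alone as
the prior, centered on the noisy observation) the latent layer cannot
correct attenuation at all.

Every coordinate block is conditionally independent across its elements
given the rest, so each block is updated with a vectorized elementwise
random-walk Metropolis step; proposal scales adapt per coordinate during
warmup (0.44 target acceptance).  The negative-binomial log-likelihood terms
that do not involve phi reduce to ``r*lm - (r+phi)*logaddexp(log phi, lm)``,
so block updates cost one logaddexp per observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = ["CNDDData", "SamplerSettings", "Priors", "run_mcmc"]


@dataclass
class CNDDData:
    """Index-aligned arrays for the sampler."""

    r: np.ndarray  # (N,) recruit counts
    pair: np.ndarray  # (N,) latent-pair index
    sp: np.ndarray  # (N,) species index
    st: np.ndarray  # (N,) station index
    cell: np.ndarray  # (N,) edge x treatment cell index
    mu0: np.ndarray  # (M,) latent prior mean, log scale
    sig0: np.ndarray  # (M,) latent prior SD, log scale
    n_species: int
    n_stations: int
    n_cells: int
    cell_labels: list
    species: list
    stations: list
    z_fixed: np.ndarray | None = None  # (M,) fixes log seed density (naive model)
    slope_group: np.ndarray | None = None  # (N,) index for u; default species

    def __post_init__(self) -> None:
        if self.slope_group is None:
            self.slope_group = self.sp
        self.n_slope_groups = int(self.slope_group.max()) + 1 if len(self.r) else 0
        if np.any(self.sig0 <= 0):
            raise ValueError("latent prior SDs must be positive")
        # center the log-density covariate so slope and intercept blocks
        # decorrelate; slopes are invariant, the intercept refers to a
        # species at the average observed log seed density.  The species
        # slope deviations use per-group centers for the same reason.
        base = self.z_fixed if self.z_fixed is not None else self.mu0
        if len(self.r):
            zb = base[self.pair]
            self.z_center = float(np.mean(zb))
            grp_sum = np.bincount(self.slope_group, weights=zb, minlength=self.n_slope_groups)
            grp_n = np.bincount(self.slope_group, minlength=self.n_slope_groups)
            self.group_center = np.where(grp_n > 0, grp_sum / np.maximum(grp_n, 1), 0.0)
        else:
            self.z_center = 0.0
            self.group_center = np.zeros(self.n_slope_groups)
        # species of each latent pair, for the population layer on z
        self.sp_of_pair = np.zeros(len(self.mu0), dtype=np.intp)
        self.sp_of_pair[self.pair] = self.sp


@dataclass
class Priors:
    """Weakly informative priors centered on 'no density dependence' (b = 1)."""

    beta_mean: float = 1.0
    beta_sd: float = 1.0
    alpha_mean: float = -1.0
    alpha_sd: float = 1.5
    sd_scale: float = 1.0  # half-normal scale for tau, sigma_sp, sigma_st
    phi_shape: float = 2.0
    phi_rate: float = 0.2
    omega_scale: float = 2.0  # half-normal scale for the population log-density SD


@dataclass
class SamplerSettings:
    chains: int = 4
    iterations: int = 2000  # total per chain, including warmup
    warmup: int = 1000
    seed: int = 0
    target_accept: float = 0.44
    refresh_every: int = 200  # full recompute of the linear predictor

    def __post_init__(self) -> None:
        if not 0 < self.warmup < self.iterations:
            raise ValueError("need 0 < warmup < iterations")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")


def _halfnormal_logpdf(x: float, scale: float) -> float:
    return -0.5 * (x / scale) ** 2


class _ChainState:
    def __init__(self, data: CNDDData, priors: Priors, rng: np.random.Generator):
        M = len(data.mu0)
        G = data.n_slope_groups
        self.alpha = priors.alpha_mean + 0.3 * rng.standard_normal()
        self.a_sp = 0.05 * rng.standard_normal(data.n_species)
        self.g_st = 0.05 * rng.standard_normal(data.n_stations)
        self.u = 0.05 * rng.standard_normal(G)
        self.beta = priors.beta_mean + 0.1 * rng.standard_normal(data.n_cells)
        if data.z_fixed is not None:
            self.z = data.z_fixed.copy()
        else:
            self.z = data.mu0 + 0.2 * data.sig0 * rng.standard_normal(M)
        self.log_tau = np.log(0.3) + 0.1 * rng.standard_normal()
        self.log_sig_sp = np.log(0.5) + 0.1 * rng.standard_normal()
        self.log_sig_st = np.log(0.5) + 0.1 * rng.standard_normal()
        self.log_phi = np.log(5.0) + 0.1 * rng.standard_normal()
        # species-level population of latent log densities
        grp_sum = np.bincount(data.sp_of_pair, weights=data.mu0, minlength=data.n_species)
        grp_n = np.maximum(np.bincount(data.sp_of_pair, minlength=data.n_species), 1)
        self.nu = grp_sum / grp_n + 0.05 * rng.standard_normal(data.n_species)
        self.log_omega = np.log(1.0) + 0.1 * rng.standard_normal()

    def linpred(self, data: CNDDData) -> np.ndarray:
        zp = self.z[data.pair]
        return (
            self.alpha + self.a_sp[data.sp] + self.g_st[data.st]
            + self.beta[data.cell] * (zp - data.z_center)
            + self.u[data.slope_group] * (zp - data.group_center[data.slope_group])
        )


def _ll_terms(r: np.ndarray, lm: np.ndarray, log_phi: float, r_plus_phi: np.ndarray) -> np.ndarray:
    # NB log-likelihood terms that vary with the linear predictor lm
    return r * lm - r_plus_phi * np.logaddexp(log_phi, lm)


def _nb_ll_full(r: np.ndarray, lm: np.ndarray, phi: float) -> float:
    lp = np.log(phi)
    t = np.logaddexp(lp, lm)
    return float(np.sum(gammaln(r + phi) - gammaln(phi) + phi * (lp - t) + r * (lm - t)))


class _AdaptiveScales:
    def __init__(self, n: int, init: float = 0.3):
        self.log_scale = np.full(n, np.log(init))
        self.t = 0

    def scales(self) -> np.ndarray:
        return np.exp(self.log_scale)

    def adapt(self, accepted: np.ndarray, target: float) -> None:
        self.t += 1
        step = min(0.25, self.t**-0.6)
        self.log_scale += step * (accepted.astype(float) - target)
        np.clip(self.log_scale, -8.0, 3.0, out=self.log_scale)


def run_mcmc(
    data: CNDDData,
    priors: Priors | None = None,
    settings: SamplerSettings | None = None,
    store_latent: bool = False,
) -> dict:
    """Sample the posterior; returns draws keyed by parameter, shaped (chain, draw, ...)."""
    priors = priors or Priors()
    settings = settings or SamplerSettings()
    n_keep = settings.iterations - settings.warmup
    C, S, J = data.n_cells, data.n_species, data.n_stations
    G = data.n_slope_groups
    M = len(data.mu0)
    r = data.r.astype(float)

    out = {
        "beta": np.empty((settings.chains, n_keep, C)),
        "u": np.empty((settings.chains, n_keep, G)),
        "alpha": np.empty((settings.chains, n_keep)),
        "tau": np.empty((settings.chains, n_keep)),
        "sigma_sp": np.empty((settings.chains, n_keep)),
        "sigma_st": np.empty((settings.chains, n_keep)),
        "phi": np.empty((settings.chains, n_keep)),
        "omega": np.empty((settings.chains, n_keep)),
        "accept_rate": np.empty(settings.chains),
    }
    if store_latent:
        out["z"] = np.empty((settings.chains, n_keep, M))

    seeds = np.random.SeedSequence(settings.seed).spawn(settings.chains)
    for chain, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        st = _ChainState(data, priors, rng)
        lm = st.linpred(data)
        scales = {
            name: _AdaptiveScales(n)
            for name, n in [
                ("z", M), ("a_sp", S), ("g_st", J), ("u", G), ("beta", C),
                ("alpha", 1), ("log_phi", 1), ("log_tau", 1),
                ("log_sig_sp", 1), ("log_sig_st", 1), ("log_omega", 1),
            ]
        }
        acc_count = 0
        acc_total = 0

        def additive_update(name: str, theta: np.ndarray, idx: np.ndarray,
                            prior_mean, prior_sd, lm: np.ndarray) -> np.ndarray:
            nonlocal acc_count, acc_total
            sc = scales[name]
            eps = sc.scales() * rng.standard_normal(len(theta))
            lm_new = lm + eps[idx]
            phi = np.exp(st.log_phi)
            d = _ll_terms(r, lm_new, st.log_phi, r + phi) - _ll_terms(
                r, lm, st.log_phi, r + phi
            )
            delta = np.bincount(idx, weights=d, minlength=len(theta))
            new = theta + eps
            delta += ((theta - prior_mean) ** 2 - (new - prior_mean) ** 2) / (
                2.0 * prior_sd**2
            )
            accept = np.log(rng.random(len(theta))) < delta
            theta += np.where(accept, eps, 0.0)
            lm += np.where(accept[idx], eps[idx], 0.0)
            if adapting:
                sc.adapt(accept, settings.target_accept)
            acc_count += int(accept.sum())
            acc_total += len(theta)
            return lm

        def slope_update(name: str, theta: np.ndarray, idx: np.ndarray,
                         prior_mean, prior_sd, lm: np.ndarray,
                         center) -> np.ndarray:
            nonlocal acc_count, acc_total
            sc = scales[name]
            eps = sc.scales() * rng.standard_normal(len(theta))
            zobs = st.z[data.pair] - center
            lm_new = lm + eps[idx] * zobs
            phi = np.exp(st.log_phi)
            d = _ll_terms(r, lm_new, st.log_phi, r + phi) - _ll_terms(
                r, lm, st.log_phi, r + phi
            )
            delta = np.bincount(idx, weights=d, minlength=len(theta))
            new = theta + eps
            delta += ((theta - prior_mean) ** 2 - (new - prior_mean) ** 2) / (
                2.0 * prior_sd**2
            )
            accept = np.log(rng.random(len(theta))) < delta
            theta += np.where(accept, eps, 0.0)
            lm += np.where(accept[idx], eps[idx] * zobs, 0.0)
            if adapting:
                sc.adapt(accept, settings.target_accept)
            acc_count += int(accept.sum())
            acc_total += len(theta)
            return lm

        def z_update(lm: np.ndarray) -> np.ndarray:
            nonlocal acc_count, acc_total
            sc = scales["z"]
            eps = sc.scales() * rng.standard_normal(M)
            slope_obs = st.beta[data.cell] + st.u[data.slope_group]
            lm_new = lm + slope_obs * eps[data.pair]
            phi = np.exp(st.log_phi)
            d = _ll_terms(r, lm_new, st.log_phi, r + phi) - _ll_terms(
                r, lm, st.log_phi, r + phi
            )
            delta = np.bincount(data.pair, weights=d, minlength=M)
            new = st.z + eps
            delta += ((st.z - data.mu0) ** 2 - (new - data.mu0) ** 2) / (
                2.0 * data.sig0**2
            )
            nu_k = st.nu[data.sp_of_pair]
            omega2 = np.exp(2.0 * st.log_omega)
            delta += ((st.z - nu_k) ** 2 - (new - nu_k) ** 2) / (2.0 * omega2)
            accept = np.log(rng.random(M)) < delta
            st.z += np.where(accept, eps, 0.0)
            lm += np.where(accept[data.pair], slope_obs * eps[data.pair], 0.0)
            if adapting:
                sc.adapt(accept, settings.target_accept)
            acc_count += int(accept.sum())
            acc_total += M
            return lm

        def scale_update(name: str, values: np.ndarray, cur_log: float,
                         scale_prior: float) -> float:
            nonlocal acc_count, acc_total
            sc = scales[name]
            prop = cur_log + sc.scales()[0] * rng.standard_normal()

            def logpost(ls: float) -> float:
                s = np.exp(ls)
                return (
                    -len(values) * ls
                    - float(np.sum(values**2)) / (2.0 * s**2)
                    + _halfnormal_logpdf(s, scale_prior)
                    + ls  # Jacobian of the log transform
                )

            accept = np.log(rng.random()) < logpost(prop) - logpost(cur_log)
            if adapting:
                sc.adapt(np.array([accept]), 0.44)
            acc_count += int(accept)
            acc_total += 1
            return prop if accept else cur_log

        def nu_gibbs() -> None:
            # conjugate update of the species population means given z
            omega2 = np.exp(2.0 * st.log_omega)
            n_s = np.maximum(np.bincount(data.sp_of_pair, minlength=S), 0)
            sum_z = np.bincount(data.sp_of_pair, weights=st.z, minlength=S)
            hyper_var = 100.0  # diffuse N(0, 10) hyperprior on nu
            prec = n_s / omega2 + 1.0 / hyper_var
            mean = (sum_z / omega2) / prec
            st.nu = mean + rng.standard_normal(S) / np.sqrt(prec)

        def omega_update() -> None:
            nonlocal acc_count, acc_total
            sc = scales["log_omega"]
            resid = st.z - st.nu[data.sp_of_pair]
            prop = st.log_omega + sc.scales()[0] * rng.standard_normal()

            def logpost(ls: float) -> float:
                s2 = np.exp(2.0 * ls)
                return (
                    -M * ls
                    - float(np.sum(resid**2)) / (2.0 * s2)
                    + _halfnormal_logpdf(np.exp(ls), priors.omega_scale)
                    + ls
                )

            accept = np.log(rng.random()) < logpost(prop) - logpost(st.log_omega)
            if accept:
                st.log_omega = prop
            if adapting:
                sc.adapt(np.array([accept]), 0.44)
            acc_count += int(accept)
            acc_total += 1

        def phi_update(lm: np.ndarray) -> None:
            nonlocal acc_count, acc_total
            sc = scales["log_phi"]
            prop = st.log_phi + sc.scales()[0] * rng.standard_normal()

            def logpost(lp: float) -> float:
                phi = np.exp(lp)
                return (
                    _nb_ll_full(r, lm, phi)
                    + priors.phi_shape * lp  # Gamma prior + Jacobian
                    - priors.phi_rate * phi
                )

            accept = np.log(rng.random()) < logpost(prop) - logpost(st.log_phi)
            if accept:
                st.log_phi = prop
            if adapting:
                sc.adapt(np.array([accept]), 0.44)
            acc_count += int(accept)
            acc_total += 1

        alpha_arr = np.array([st.alpha])
        zero_idx = np.zeros(len(r), dtype=np.intp)
        for it in range(settings.iterations):
            adapting = it < settings.warmup
            if it % settings.refresh_every == 0:
                lm = st.linpred(data)
            if data.z_fixed is None:
                lm = z_update(lm)
                nu_gibbs()
                omega_update()
            lm = additive_update("a_sp", st.a_sp, data.sp, 0.0,
                                 np.exp(st.log_sig_sp), lm)
            lm = additive_update("g_st", st.g_st, data.st, 0.0,
                                 np.exp(st.log_sig_st), lm)
            alpha_arr[0] = st.alpha
            lm = additive_update("alpha", alpha_arr, zero_idx,
                                 priors.alpha_mean, priors.alpha_sd, lm)
            st.alpha = alpha_arr[0]
            lm = slope_update("beta", st.beta, data.cell, priors.beta_mean,
                              priors.beta_sd, lm, data.z_center)
            lm = slope_update("u", st.u, data.slope_group, 0.0,
                              np.exp(st.log_tau), lm,
                              data.group_center[data.slope_group])
            phi_update(lm)
            st.log_tau = scale_update("log_tau", st.u, st.log_tau, priors.sd_scale)
            st.log_sig_sp = scale_update("log_sig_sp", st.a_sp, st.log_sig_sp,
                                         priors.sd_scale)
            st.log_sig_st = scale_update("log_sig_st", st.g_st, st.log_sig_st,
                                         priors.sd_scale)

            if it >= settings.warmup:
                k = it - settings.warmup
                out["beta"][chain, k] = st.beta
                out["u"][chain, k] = st.u
                out["alpha"][chain, k] = st.alpha
                out["tau"][chain, k] = np.exp(st.log_tau)
                out["sigma_sp"][chain, k] = np.exp(st.log_sig_sp)
                out["sigma_st"][chain, k] = np.exp(st.log_sig_st)
                out["phi"][chain, k] = np.exp(st.log_phi)
                out["omega"][chain, k] = np.exp(st.log_omega)
                if store_latent:
                    out["z"][chain, k] = st.z
        out["accept_rate"][chain] = acc_count / max(acc_total, 1)
    return out
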
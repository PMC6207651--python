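"""Species filters, trap-moment matching, and CNDD posterior summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import edgecndd as ec
from edgecndd.cndd import CNDDPosterior, CNDDModelSpec


def _toy_tables(station_densities, seedlings_total, sp="spA", n_fill_stations=0):
    """Trap/plot tables for one species with given per-station pair totals."""
    trows, prows = [], []
    for j, dens in enumerate(station_densities):
        sid = f"s{j}"
        trows.append((sid, 1, sp, int(np.ceil(dens))))
        trows.append((sid, 2, sp, int(np.floor(dens))))
    per = seedlings_total // max(len(station_densities), 1)
    rem = seedlings_total - per * len(station_densities)
    for j in range(len(station_densities)):
        sid = f"s{j}"
        n = per + (1 if j < rem else 0)
        if n > 0:
            prows.append((f"{sid}-P1", sid, "control", sp, n))
    traps = pd.DataFrame(trows, columns=["station_id", "trap_id", "species_id", "count"])
    plots = pd.DataFrame(prows, columns=["plot_id", "station_id", "treatment",
                                         "species_id", "recruits"])
    return traps, plots


class TestFilterSpecies:
    def test_species_meeting_all_rules_retained(self):
        traps, plots = _toy_tables([2, 3, 4, 5, 6, 7, 8, 9, 10, 10, 4, 6], 8)
        species, report = ec.filter_species(traps, plots)
        assert species == ["spA"]
        assert report["retained"].all()

    def test_too_few_seedlings_excluded(self):
        traps, plots = _toy_tables([2, 3, 4, 5, 6, 7, 8, 9, 10, 10, 4, 6], 8)
        t2, p2 = _toy_tables([2, 3, 4, 5, 6, 7, 8, 9, 10, 10, 4, 6], 4, sp="spB")
        species, report = ec.filter_species(
            pd.concat([traps, t2]), pd.concat([plots, p2])
        )
        assert species == ["spA"]
        assert "seedlings<5" in report.set_index("species_id").loc["spB", "reason"]

    def test_too_few_stations_excluded(self):
        traps, plots = _toy_tables([2, 3, 4, 5, 6, 7, 8, 9, 10], 9)  # 9 stations
        with pytest.raises(ValueError, match="retained no species"):
            ec.filter_species(traps, plots)

    def test_insufficient_density_variation_excluded(self):
        traps, plots = _toy_tables([5] * 12, 12)  # fold change 1 < 3
        with pytest.raises(ValueError, match="retained no species"):
            ec.filter_species(traps, plots)


class TestTrapMoments:
    def test_worked_example_moment_match(self):
        # trap counts 8 -/+ sqrt(8) have sample mean 8 and sample variance 16
        mu, sigma, prov = ec.trap_moments_to_lognormal(8 - np.sqrt(8), 8 + np.sqrt(8))
        assert sigma**2 == pytest.approx(np.log(1.25), rel=1e-9)
        assert mu == pytest.approx(np.log(8) - np.log(1.25) / 2, rel=1e-9)
        assert mu == pytest.approx(1.96787, abs=1e-4)
        assert prov == "from_traps"

    def test_zero_traps_imputed_from_seedlings(self):
        mu, sigma, prov = ec.trap_moments_to_lognormal(0, 0, seedlings=4)
        assert prov == "imputed_from_seedlings"
        assert sigma**2 == pytest.approx(np.log(1.25), rel=1e-9)
        assert mu == pytest.approx(1.27472, abs=1e-4)

    def test_equal_traps_hit_variance_floor(self):
        mu, sigma, prov = ec.trap_moments_to_lognormal(5, 5)
        assert sigma > 0
        assert sigma**2 == pytest.approx(np.log(1 + 0.25 / 25), rel=1e-9)

    def test_no_information_pair_dropped(self):
        assert ec.trap_moments_to_lognormal(0, 0, seedlings=0) is None

    @pytest.mark.parametrize("t1,t2", [(3, 9), (1, 0), (20, 14), (2, 2)])
    def test_implied_lognormal_moments_exact(self, t1, t2):
        mu, sigma, _ = ec.trap_moments_to_lognormal(t1, t2)
        m = (t1 + t2) / 2
        v_eff = max((t1 - t2) ** 2 / 2, 0.25)
        # closed-form lognormal moments
        assert np.exp(mu + sigma**2 / 2) == pytest.approx(m, rel=1e-9)
        implied_var = (np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2)
        assert implied_var == pytest.approx(v_eff, rel=1e-9)
        # and by quadrature, independently of the closed form
        mean_q, _ = integrate.quad(
            lambda x: x * stats.lognorm.pdf(x, s=sigma, scale=np.exp(mu)), 0, np.inf
        )
        assert mean_q == pytest.approx(m, rel=1e-6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ec.trap_moments_to_lognormal(-1, 2)


class TestBuildLatentPriors:
    def test_only_informative_pairs_kept(self):
        traps = pd.DataFrame(
            [("s0", 1, "spA", 3), ("s0", 2, "spA", 5)],
            columns=["station_id", "trap_id", "species_id", "count"],
        )
        plots = pd.DataFrame(
            [("s1-P1", "s1", "control", "spA", 2)],
            columns=["plot_id", "station_id", "treatment", "species_id", "recruits"],
        )
        stations = pd.DataFrame(
            {"station_id": ["s0", "s1", "s2"], "location_id": "L", "edge_category": "E0"}
        )
        pt = ec.build_latent_priors(traps, plots, stations, ["spA"])
        assert set(pt["station_id"]) == {"s0", "s1"}  # s2: no info
        prov = pt.set_index("station_id")["provenance"]
        assert prov["s0"] == "from_traps"
        assert prov["s1"] == "imputed_from_seedlings"


def _degenerate_posterior(b_values, n_cells=1):
    chains, draws = 2, 50
    beta = np.tile(np.asarray(b_values, float), (chains, draws, 1))
    u = np.zeros((chains, draws, 3))
    zero = np.zeros((chains, draws))
    return CNDDPosterior(
        draws={"beta": beta, "u": u, "alpha": zero, "tau": zero, "phi": zero + 1,
               "sigma_sp": zero, "sigma_st": zero, "omega": zero + 1,
               "accept_rate": np.array([0.4, 0.4])},
        cell_labels=[("E0", "control")] * beta.shape[2],
        species=["a", "b", "c"],
        stations=["s0"],
        diagnostics={},
        spec=CNDDModelSpec(),
        corrected=True,
    )


class TestSummarizeCNDD:
    def test_point_mass_posterior(self):
        post = _degenerate_posterior([0.8])
        s = ec.summarize_cndd(post)
        assert s["mean_b"].iloc[0] == pytest.approx(0.8)
        assert s["ci_low"].iloc[0] == pytest.approx(0.8)
        assert s["ci_high"].iloc[0] == pytest.approx(0.8)
        assert bool(s["cndd_flag"].iloc[0])

    def test_draws_symmetric_around_one_not_flagged(self):
        post = _degenerate_posterior([1.0])
        rng = np.random.default_rng(0)
        post.draws["beta"] = 1.0 + 0.2 * rng.standard_normal((2, 400, 1))
        post.draws["u"] = np.zeros((2, 400, 3))
        s = ec.summarize_cndd(post)
        assert not bool(s["cndd_flag"].iloc[0])
        assert s["mean_b"].iloc[0] == pytest.approx(1.0, abs=0.05)

    def test_summary_recomputable_from_long_draws(self):
        post = _degenerate_posterior([0.9])
        rng = np.random.default_rng(1)
        post.draws["beta"] = 0.9 + 0.1 * rng.standard_normal((2, 50, 1))
        s = ec.summarize_cndd(post)
        long = post.to_long_draws()
        beta_long = long[long["parameter"] == "beta[E0:control]"]["value"].to_numpy()
        u_cols = [f"u[{i}]" for i in range(3)]
        u_long = np.stack(
            [long[long["parameter"] == c]["value"].to_numpy() for c in u_cols]
        )
        recomputed = beta_long + u_long.mean(axis=0)
        assert s["mean_b"].iloc[0] == pytest.approx(recomputed.mean(), rel=1e-12)
        assert s["ci_low"].iloc[0] == pytest.approx(
            np.quantile(recomputed, 0.025), rel=1e-9
        )
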
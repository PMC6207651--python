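"""Seed-rain and recruitment simulation: moments, determinism, round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import edgecndd as ec
from conftest import single_cell_design


def _trap_matrix(traps, design, species):
    """Dense station x species matrix of summed trap counts."""
    full = traps.pivot_table(index="station_id", columns="species_id",
                             values="count", aggfunc="sum", fill_value=0)
    return full.reindex(index=design.stations["station_id"], columns=species,
                        fill_value=0)


class TestSeedRain:
    def test_trap_counts_poisson_around_constant_density(self):
        # no station variation: every trap is Poisson(lam_s); check first moments
        dc = single_cell_design(n_locations=2000, replicates=1)
        cp = ec.CommunityParams(
            n_species=1, abundance_distribution="log_series", abundance_shape=0.5,
            total_seed_density=4.0, seed_density_lognormal_sd=0.0, rng_seed=8,
        )
        design, truth, traps, _ = ec.simulate_dataset(dc, cp)
        lam = truth.lam.iloc[0, 0]
        assert lam == pytest.approx(4.0)
        pair_mean = _trap_matrix(traps, design, truth.species).to_numpy().ravel() / 2.0
        se = np.sqrt(lam / (2 * len(design.stations)))  # var of a pair mean is lam/2
        assert abs(pair_mean.mean() - lam) < 3 * se

    def test_zero_density_species_never_counted(self):
        cp = ec.CommunityParams(n_species=3, total_seed_density=0.0, rng_seed=1)
        design = ec.generate_design(single_cell_design(5, 1))
        _, traps = ec.simulate_seed_rain(design, cp)
        assert len(traps) == 0

    def test_trap_pair_mean_unbiased_for_latent_density(self):
        dc = single_cell_design(n_locations=3000, replicates=1)
        cp = ec.CommunityParams(n_species=1, abundance_shape=0.5,
                                total_seed_density=6.0,
                                seed_density_lognormal_sd=0.7, rng_seed=5)
        design, truth, traps, _ = ec.simulate_dataset(dc, cp)
        pair_mean = _trap_matrix(traps, design, truth.species).to_numpy().ravel() / 2.0
        lam = truth.lam.to_numpy().ravel()
        diff = pair_mean - lam
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se + 1e-9

    def test_seed_rain_reproducible_bit_for_bit(self):
        dc = single_cell_design(5, 2)
        cp = ec.CommunityParams(n_species=10, rng_seed=99)
        d1, t1, tr1, p1 = ec.simulate_dataset(dc, cp)
        d2, t2, tr2, p2 = ec.simulate_dataset(dc, cp)
        pd.testing.assert_frame_equal(tr1, tr2)
        pd.testing.assert_frame_equal(p1, p2)
        assert t1.lam.equals(t2.lam)


class TestRecruitment:
    @pytest.mark.parametrize("a,b,lam,expected", [
        (0.2, 1.0, 50.0, 10.0),   # b = 1: proportional transition, no CNDD
        (1.0, 0.5, 100.0, 10.0),  # sqrt law
    ])
    def test_mean_recruits_follow_power_law(self, a, b, lam, expected):
        rng = np.random.default_rng(0)
        phi = 5.0
        mean = a * lam**b
        assert mean == pytest.approx(expected)
        draws = rng.negative_binomial(phi, phi / (phi + mean), size=40000)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3.5 * se

    def test_large_dispersion_approaches_poisson(self):
        # NB(mean, size) -> Poisson(mean) as size -> infinity
        rng = np.random.default_rng(1)
        phi, mean = 2e5, 7.0
        draws = rng.negative_binomial(phi, phi / (phi + mean), size=10000)
        assert draws.var(ddof=1) == pytest.approx(mean, rel=0.08)

    def test_simulated_slope_matches_truth_when_b_is_one(self):
        # with b = 1 the log of mean recruits is linear in log density, slope 1
        dc = single_cell_design(n_locations=400, replicates=1)
        cp = ec.CommunityParams(n_species=8, abundance_shape=0.8,
                                total_seed_density=100.0,
                                seed_density_lognormal_sd=0.0,
                                species_slope_sd=0.0, b_matrix=1.0,
                                nb_dispersion=50.0, rng_seed=21)
        design, truth, traps, plots = ec.simulate_dataset(dc, cp)
        lam_s = truth.lam.iloc[0]  # constant across stations
        mean_rec = (
            plots.groupby("species_id")["recruits"].sum()
            .reindex(lam_s.index).fillna(0) / len(design.stations)
        )
        keep = mean_rec > 0
        slope = np.polyfit(np.log(lam_s[keep]), np.log(mean_rec[keep]), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_zero_density_means_zero_recruits(self):
        design = ec.generate_design(single_cell_design(4, 1))
        cp = ec.CommunityParams(n_species=2, total_seed_density=0.0, rng_seed=2)
        truth, _ = ec.simulate_seed_rain(design, cp)
        plots = ec.simulate_recruitment(truth, design)
        assert len(plots) == 0


class TestWriteDataset:
    def test_round_trip_preserves_tables(self, small_dataset, tmp_path):
        design, truth, traps, plots = small_dataset
        ec.write_dataset(design, traps, plots, truth, tmp_path)
        stations, traps2, plots2 = ec.read_tables(tmp_path)
        pd.testing.assert_frame_equal(stations, design.stations)
        pd.testing.assert_frame_equal(
            traps2.reset_index(drop=True), traps.reset_index(drop=True),
            check_dtype=False,
        )
        counted = plots2[plots2["species_id"] != ""].reset_index(drop=True)
        pd.testing.assert_frame_equal(
            counted[["plot_id", "species_id", "recruits"]],
            plots[["plot_id", "species_id", "recruits"]].reset_index(drop=True),
            check_dtype=False,
        )

    def test_truth_json_contains_full_b_matrix(self, small_dataset, tmp_path):
        design, truth, traps, plots = small_dataset
        ec.write_dataset(design, traps, plots, truth, tmp_path)
        t2 = ec.GroundTruth.from_json((tmp_path / "truth.json").read_text())
        assert t2.b_cell.equals(truth.b_cell)
        assert np.allclose(t2.lam.to_numpy(), truth.lam.to_numpy())

    def test_refuses_overwrite_without_flag(self, small_dataset, tmp_path):
        design, truth, traps, plots = small_dataset
        ec.write_dataset(design, truth=truth, traps=traps, plots=plots,
                         directory=tmp_path)
        with pytest.raises(FileExistsError):
            ec.write_dataset(design, traps, plots, truth, tmp_path)
        ec.write_dataset(design, traps, plots, truth, tmp_path, overwrite=True)

    def test_plot_metadata_rows_equal_design(self, small_dataset, tmp_path):
        design, truth, traps, plots = small_dataset
        ec.write_dataset(design, traps, plots, truth, tmp_path)
        text = (tmp_path / "plots.csv").read_text().strip().splitlines()
        meta_rows = [l for l in text[1:] if l.split(",")[3] == ""]
        assert len(meta_rows) == len(design.plots)
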
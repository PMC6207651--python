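"""Hill-number indices: closed forms, rarefaction oracle, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import edgecndd as ec
from edgecndd.diversity import INDEX_NAMES

count_vectors = st.lists(st.integers(0, 50), min_size=1, max_size=12).filter(
    lambda v: sum(v) > 0
)


class TestInverseSimpson:
    def test_worked_example(self):
        assert ec.inverse_simpson([5, 3, 2]) == pytest.approx(1 / 0.38, rel=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 7])
    def test_equal_abundances_give_species_count(self, k):
        assert ec.inverse_simpson([13] * k) == pytest.approx(k, rel=1e-12)

    def test_empty_assemblage_is_missing(self):
        assert math.isnan(ec.inverse_simpson([0, 0]))


class TestExpShannon:
    def test_worked_example(self):
        p = np.array([5, 3, 2]) / 10
        expected = math.exp(-(p * np.log(p)).sum())
        assert expected == pytest.approx(2.8001, abs=1e-4)
        assert ec.exp_shannon([5, 3, 2]) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("k", [1, 3, 9])
    def test_equal_abundances_give_species_count(self, k):
        assert ec.exp_shannon([4] * k) == pytest.approx(k, rel=1e-12)

    def test_single_species_has_unit_diversity(self):
        assert ec.exp_shannon([17]) == pytest.approx(1.0)


class TestRarefiedRichness:
    def test_two_pairs_subsample_two(self):
        # brute force: C(4,2)=6 subsamples, 5 contain both species
        assert ec.rarefied_richness([2, 2], 2) == pytest.approx(5 / 3, rel=1e-12)

    def test_full_sample_returns_observed_richness(self):
        v = [4, 1, 2]
        assert ec.rarefied_richness(v, sum(v)) == pytest.approx(3.0, rel=1e-12)

    def test_insufficient_individuals_is_missing(self):
        assert math.isnan(ec.rarefied_richness([1, 1], 5))

    def test_matches_monte_carlo_subsampling(self):
        rng = np.random.default_rng(12)
        for _ in range(15):
            v = rng.integers(0, 8, size=rng.integers(2, 6))
            n = int(rng.integers(1, 5))
            if v.sum() < n:
                continue
            individuals = np.repeat(np.arange(len(v)), v)
            n_rep = 4000
            order = np.argsort(rng.random((n_rep, len(individuals))), axis=1)[:, :n]
            picked = individuals[order]
            richness = (np.sort(picked, axis=1)[:, 1:] != np.sort(picked, axis=1)[:, :-1]).sum(axis=1) + 1
            mc = richness.mean()
            se = richness.std(ddof=1) / np.sqrt(n_rep)
            assert abs(ec.rarefied_richness(v, n) - mc) < 3 * se + 1e-9


class TestIndexProperties:
    @given(count_vectors)
    def test_hill_ordering(self, v):
        richness = sum(1 for c in v if c > 0)
        e = ec.exp_shannon(v)
        i = ec.inverse_simpson(v)
        assert richness + 1e-9 >= e >= i - 1e-9
        assert i >= 1.0 - 1e-12

    @given(count_vectors, st.integers(2, 6))
    def test_ratio_indices_invariant_to_relabeling_and_scaling(self, v, factor):
        perm = np.random.default_rng(0).permutation(len(v))
        shuffled = [v[i] for i in perm]
        scaled = [c * factor for c in v]
        for f in (ec.inverse_simpson, ec.exp_shannon):
            assert f(shuffled) == pytest.approx(f(v), rel=1e-9)
            assert f(scaled) == pytest.approx(f(v), rel=1e-9)


class TestPoolControls:
    def _table(self, rows):
        import pandas as pd

        return pd.DataFrame(
            rows,
            columns=["unit_id", "unit_kind", "station_id", "treatment",
                     "edge_category", "index", "value"],
        )

    def test_control_water_mean(self):
        t = self._table([
            ("p1", "seedling", "s1", "control", "E0", "inverse_simpson", 3.0),
            ("p2", "seedling", "s1", "water", "E0", "inverse_simpson", 2.0),
        ])
        pooled = ec.pool_controls(t)
        row = pooled[pooled["treatment"] == "Control"].iloc[0]
        assert row["value"] == pytest.approx(2.5)
        assert not row["pooled_flag"]

    def test_identical_values_pass_through(self):
        t = self._table([
            ("p1", "seedling", "s1", "control", "E0", "inverse_simpson", 4.1),
            ("p2", "seedling", "s1", "water", "E0", "inverse_simpson", 4.1),
        ])
        row = ec.pool_controls(t)
        assert row[row["treatment"] == "Control"]["value"].iloc[0] == pytest.approx(4.1)

    def test_missing_water_plot_uses_single_value_with_flag(self):
        t = self._table([
            ("p1", "seedling", "s1", "control", "E0", "inverse_simpson", 3.0),
        ])
        row = ec.pool_controls(t)[lambda d: d["treatment"] == "Control"].iloc[0]
        assert row["value"] == pytest.approx(3.0)
        assert row["pooled_flag"]

    def test_other_treatments_unchanged(self):
        t = self._table([
            ("p1", "seedling", "s1", "control", "E0", "inverse_simpson", 3.0),
            ("p2", "seedling", "s1", "water", "E0", "inverse_simpson", 2.0),
            ("p3", "seedling", "s1", "fungicide", "E0", "inverse_simpson", 6.0),
        ])
        pooled = ec.pool_controls(t)
        assert pooled[pooled["treatment"] == "fungicide"]["value"].iloc[0] == 6.0


class TestDiversityTable:
    def test_all_indices_present_per_unit(self, small_dataset):
        design, truth, traps, plots = small_dataset
        dt = ec.diversity_table(traps, plots, design.stations)
        per_unit = dt.groupby("unit_id")["index"].nunique()
        assert (per_unit == len(INDEX_NAMES)).all()
        n_units = len(design.plots) + len(design.stations)
        assert dt["unit_id"].nunique() == n_units

    def test_seed_rows_use_pooled_traps(self, small_dataset):
        design, truth, traps, plots = small_dataset
        dt = ec.diversity_table(traps, plots, design.stations)
        sid = design.stations["station_id"].iloc[0]
        pooled = traps[traps["station_id"] == sid].groupby("species_id")["count"].sum()
        expected = ec.inverse_simpson(pooled.to_numpy())
        got = dt[(dt["unit_id"] == sid) & (dt["index"] == "inverse_simpson")]["value"].iloc[0]
        assert got == pytest.approx(expected)
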
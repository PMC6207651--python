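import warnings

import pytest
from hypothesis import HealthCheck, settings

import edgecndd as ec

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_model_warnings():
    # statsmodels mixed fits routinely warn about boundary variance estimates
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="statsmodels")
        warnings.filterwarnings("ignore", category=FutureWarning)
        yield


@pytest.fixture(scope="session")
def small_dataset():
    """A compact full-design dataset shared by read-only tests."""
    dc = ec.DesignConfig(
        n_locations=6, replicates_per_distance=2, n_e3_stations=6, n_e3_locations=3
    )
    cp = ec.CommunityParams(n_species=15, rng_seed=42)
    design, truth, traps, plots = ec.simulate_dataset(dc, cp)
    return design, truth, traps, plots


def single_cell_design(n_locations=20, replicates=3):
    """One edge band, one control plot per station: the simplest CNDD layout."""
    return ec.DesignConfig(
        n_locations=n_locations,
        replicates_per_distance=replicates,
        n_e3_stations=0,
        treatments=("control",),
        near_edge_categories=("E0",),
    )
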
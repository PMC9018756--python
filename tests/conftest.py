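import pytest

from diglyquant.synthetic_data import SimConfig, simulate_dataset
from diglyquant.tables_io import filter_rows


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def default_bundle(default_config):
    """One full-size simulated experiment shared across tests."""
    return simulate_dataset(default_config)


@pytest.fixture(scope="session")
def filtered_bundle(default_bundle):
    bundle, truth = default_bundle
    return filter_rows(bundle.sites), filter_rows(bundle.proteins), truth


@pytest.fixture(scope="session")
def small_bundle():
    """A fast, small experiment for structural checks."""
    cfg = SimConfig(n_proteins=150, seed=11)
    return simulate_dataset(cfg), cfg
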
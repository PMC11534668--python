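import pytest

from faerspv.synthetic import SimConfig, catalog_dictionary, simulate_reports


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated extract shared by read-only tests."""
    config = SimConfig(n_cases_target=400, n_cases_background=400, seed=11)
    tables, truth = simulate_reports(config)
    return config, tables, truth


@pytest.fixture(scope="session")
def small_dictionary(small_sim):
    config, _, _ = small_sim
    return catalog_dictionary(config)
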
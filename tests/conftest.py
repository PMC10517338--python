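import pytest

from utrcensus.synthetic_data import SimulationConfig, simulate_annotation, simulate_benchmark


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def annotation(sim_config):
    return simulate_annotation(sim_config)


@pytest.fixture(scope="session")
def benchmark_sim(sim_config):
    return simulate_benchmark(sim_config)
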
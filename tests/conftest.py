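import numpy as np
import pytest

from panrep import SimulationConfig, generate_library, simulate_biopanning


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast simulation used by several suites."""
    return SimulationConfig(
        seed=11,
        n_clones=200,
        n_binders_per_subtype=5,
        reads_per_sample=300,
        n_replicates=1,
    )


@pytest.fixture(scope="session")
def tiny_library(tiny_config):
    return generate_library(tiny_config)


@pytest.fixture(scope="session")
def tiny_simulation(tiny_config, tiny_library):
    return simulate_biopanning(tiny_config, tiny_library)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
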
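import numpy as np
import pytest

from dualgene.simulate import SimulationConfig, generate_universe


@pytest.fixture
def small_config():
    return SimulationConfig(
        n_genes={"POTSF": 20, "ONC": 30, "TSG": 25, "NCRG": 40},
        cohorts={"A": 50, "B": 60},
        seed=3,
    )


@pytest.fixture
def small_partition(small_config):
    return generate_universe(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
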
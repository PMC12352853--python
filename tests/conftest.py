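import numpy as np
import pytest

from allomflow import SimulationConfig, simulate_network


@pytest.fixture(scope="session")
def cascade_nodes():
    """Symmetric noiseless cascade: 2^11 - 1 internodes at exact half-area splits."""
    cfg = SimulationConfig(
        mode="branching_cascade", base_radius=32.0, radius_floor=1.0, seed=11, n_trees=1
    )
    return simulate_network(cfg)


@pytest.fixture(scope="session")
def noisy_cascade_nodes():
    cfg = SimulationConfig(
        mode="branching_cascade",
        base_radius=60.0,
        radius_floor=0.8,
        seed=17,
        n_trees=2,
        ratio_noise_sd0=0.25,
        ratio_noise_radius_exp=0.3,
    )
    return simulate_network(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
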
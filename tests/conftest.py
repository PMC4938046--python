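import numpy as np
import pytest

from beelearn.sim import WorldConfig
from beelearn.synth import GeneratorConfig, generate_choice_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_world():
    """A fast world for structural tests: 5 patches, 20 agents, 200 steps."""
    return WorldConfig(
        n_patches=5,
        n_agents=20,
        total_resource=10.0,
        n_rich_patches=2,
        turnover_interval=5,
        n_steps=200,
        burn_in_fraction=0.5,
    )


@pytest.fixture(scope="session")
def default_records():
    """The default 57-bee synthetic dataset (seed 1)."""
    return generate_choice_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def forty_bee_records():
    """A fixed 40-bee balanced dataset used for the mixed-model oracle checks."""
    config = GeneratorConfig(
        group_sizes={(1, 0): 10, (1, 1): 10, (0, 0): 10, (0, 1): 10},
        colony_sd=0.5,
        seed=1,
    )
    return generate_choice_dataset(config)
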
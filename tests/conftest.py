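import numpy as np
import pytest

from mtgwas.simulate import SimulationConfig, make_synthetic_manifest


@pytest.fixture
def small_manifest():
    return make_synthetic_manifest("chipT", 30, n_measures=3, seed=101)


@pytest.fixture
def base_config(small_manifest):
    return SimulationConfig(seed=5, n_individuals=150, manifest=small_manifest)


@pytest.fixture
def rng():
    return np.random.default_rng(424242)
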
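import numpy as np
import pytest

from rabswitch.model_space import default_library, enumerate_structures
from rabswitch.synthetic_data import default_switch_scenario, generate


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def all_structures(library):
    return enumerate_structures(library=library)


@pytest.fixture(scope="session")
def truth_spec():
    """Noiseless desk-scale instance of the reference switch scenario."""
    return default_switch_scenario(n_points=300, noise_level=0.0)


@pytest.fixture(scope="session")
def small_data(truth_spec):
    dataset, truth = generate(truth_spec)
    return dataset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
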
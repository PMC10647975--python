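import numpy as np
import pytest

from hepamap import CohortConfig, make_phantom_truth


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(shape=(24, 24, 4), seed=0)


@pytest.fixture(scope="session")
def healthy_truth(small_config):
    return make_phantom_truth(small_config, "healthy", seed=1)


@pytest.fixture(scope="session")
def patient_truth(small_config):
    return make_phantom_truth(small_config, "patient", seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
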
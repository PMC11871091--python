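import numpy as np
import pytest

from hipseg.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def clean_config():
    return PhantomConfig(noise_sigma=0.0, seed=7)


@pytest.fixture(scope="session")
def noisy_config():
    return PhantomConfig(noise_sigma=10.0, seed=7)


@pytest.fixture(scope="session")
def clean_sample(clean_config):
    return generate_phantom(clean_config, "S0000")


@pytest.fixture(scope="session")
def noisy_sample(noisy_config):
    return generate_phantom(noisy_config, "S0000")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
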
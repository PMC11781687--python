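import numpy as np
import pytest

from asgcl import SyntheticSpec, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact planted-signal dataset that trains in under a second."""
    spec = SyntheticSpec(m=40, n=15, r=3, signal=3.0, feature_dims=(30, 16),
                        noise_sd=0.5, density_bias=-0.5, seed=11)
    dataset, latent = simulate_dataset(spec)
    return dataset, latent


@pytest.fixture(scope="session")
def standard_dataset():
    from asgcl import standard_fixture
    return standard_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
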
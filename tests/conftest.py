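import numpy as np
import pytest

from noduleseg import phantom


@pytest.fixture(scope="session")
def noiseless_sample():
    spec = phantom.PhantomSpec(noise_sigma=0.0, n_nodules=2, rng_seed=3)
    return phantom.generate_slice(spec)


@pytest.fixture(scope="session")
def noisy_sample():
    spec = phantom.PhantomSpec(noise_sigma=0.02, n_nodules=2, rng_seed=7)
    return phantom.generate_slice(spec)


@pytest.fixture(scope="session")
def volume_dataset():
    """50 volumes per class, the scale used for classifier checks."""
    return phantom.generate_dataset(50, rng_seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
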
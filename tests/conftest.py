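import numpy as np
import pytest

from renovol.imaging import ClassScheme
from renovol.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def post_phantom():
    """One default post-contrast phantom with its ground truth (session-cached)."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(PhantomSpec(seed=3, noise_sigma=0.0))


@pytest.fixture(scope="session")
def pre_phantom():
    return generate_phantom(PhantomSpec(seed=5, phase="pre_contrast"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def post_scheme():
    return ClassScheme.post_contrast()


@pytest.fixture
def pre_scheme():
    return ClassScheme.pre_contrast()
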
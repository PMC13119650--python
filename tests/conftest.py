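import numpy as np
import pytest

from haaunet.phantoms import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default phantom: (image, labels)."""
    spec = PhantomSpec(noise_sd=0.0, seed=0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(noise_sd=15.0, seed=3)
    return generate_phantom(spec)
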
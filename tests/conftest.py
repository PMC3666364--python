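import numpy as np
import pytest

from somseg.io_volume import Volume
from somseg.synthetic import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """16^3 noiseless-ish phantom shared by fast tests."""
    return make_phantom(PhantomSpec(shape=(16, 16, 16), noise_sigma=2.0, seed=7))


@pytest.fixture(scope="session")
def noisy_phantom():
    """32^3 phantom at the canonical contrast/noise settings."""
    return make_phantom(
        PhantomSpec(shape=(32, 32, 32), tissue_means=(30, 100, 180), noise_sigma=10, seed=3)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume(rng):
    """8^3 random-intensity volume, fully masked."""
    data = rng.uniform(0, 255, size=(8, 8, 8))
    return Volume(data=data, mask=np.ones((8, 8, 8), dtype=bool))
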
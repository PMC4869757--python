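import numpy as np
import pytest

from petmrcorr import ImageGrid, PhantomConfig, make_phantom

PET_GRID = ImageGrid((36, 36, 26), (2.8, 2.8, 2.0))


@pytest.fixture(scope="session")
def pet_grid():
    return PET_GRID


@pytest.fixture(scope="session")
def noiseless_phantom():
    """One noise-free phantom patient at the default study conditions."""
    return make_phantom(PhantomConfig(seed=42, noise=None))


@pytest.fixture(scope="session")
def noisy_phantom():
    return make_phantom(PhantomConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
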
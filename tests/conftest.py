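import numpy as np
import pytest

from hemoct.phantom import PhantomConfig
from hemoct.volumes import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume(rng):
    return Volume(
        rng.uniform(0.0, 100.0, size=(9, 8, 6)),
        spacing=(1.5, 1.5, 5.0),
        label="SAH",
        source_id="vol0",
    )


@pytest.fixture
def small_phantom_config():
    """Small, fast phantom grid for structural tests."""
    return PhantomConfig(shape=(24, 24, 12), seed=3)


@pytest.fixture
def noiseless_config():
    return PhantomConfig(noise_sd=0.0, seed=3)
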
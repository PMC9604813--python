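import numpy as np
import pytest

from spinerecon.dataset import DatasetConfig, build_phantom_dataset
from spinerecon.phantoms import PhantomConfig, make_phantom


@pytest.fixture(scope="session")
def desk_phantom():
    """One small seeded phantom volume with labels."""
    return make_phantom(PhantomConfig(shape=(64, 64, 96), spacing=2.0, rng_seed=11))


@pytest.fixture(scope="session")
def desk_samples():
    """Ten reconstruction samples (2 phantoms x 5 levels) at desk scale."""
    return build_phantom_dataset(DatasetConfig.desk(n_phantoms=2, rng_seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
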
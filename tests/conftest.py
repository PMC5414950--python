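import numpy as np
import pytest

from rangealign.grid import make_grid
from rangealign.synthetic import SimConfig


@pytest.fixture(scope="session")
def grid():
    return make_grid(0.5)


@pytest.fixture(scope="session")
def coarse_grid():
    return make_grid(1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=11, n_species=25)
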
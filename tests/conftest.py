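import numpy as np
import pytest

from elecloc import RegOptions, register_rigid
from elecloc.fixtures import (
    PhantomSpec,
    make_head_phantom,
    make_parcellation_fixture,
    make_pial_fixture,
    make_warp_fixture,
)

PHANTOM_SEED = 3
PIAL_SEED = 7
PARC_SEED = 5
WARP_SEED = 11


@pytest.fixture(scope="session")
def phantom():
    """Default 96 mm-cube head phantom with the standard displacement."""
    return make_head_phantom(PhantomSpec(seed=PHANTOM_SEED))


@pytest.fixture(scope="session")
def registered(phantom):
    """Rigid registration of the phantom CT to the phantom T1 (run once)."""
    t = register_rigid(phantom["t1"], phantom["ct"], opts=RegOptions(seed=0))
    return t


@pytest.fixture(scope="session")
def pial_fix():
    return make_pial_fixture(seed=PIAL_SEED)


@pytest.fixture(scope="session")
def parc_fix():
    return make_parcellation_fixture(seed=PARC_SEED)


@pytest.fixture(scope="session")
def warp_fix():
    return make_warp_fixture(seed=WARP_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
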
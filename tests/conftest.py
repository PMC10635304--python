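import numpy as np
import pytest

from synthcest.params import AcquisitionParams, PoolParams
from synthcest.bloch import PoolSet, default_brain_pools


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def water_pool():
    return PoolParams("water", 1.0, 0.0, 0.0, R1s=1.0 / 1.8, R2s=1.0 / 0.05)


@pytest.fixture(scope="session")
def water_only(water_pool):
    return PoolSet(water=water_pool)


@pytest.fixture(scope="session")
def amide_pool():
    return PoolParams("amide", 1.0e-3, 50.0, 3.5, R1s=1.0, R2s=30.0)


@pytest.fixture(scope="session")
def two_pool(water_pool, amide_pool):
    return PoolSet(water=water_pool, solutes=(amide_pool,))


@pytest.fixture(scope="session")
def brain_pools():
    return default_brain_pools()
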
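import numpy as np
import pytest

from slicedwi import phantom as ph
from slicedwi import schedule as sch


@pytest.fixture(scope="session")
def small_geometry():
    return sch.AcquisitionGeometry(n_slices=12, tr=3.0)


@pytest.fixture(scope="session")
def small_schedule(small_geometry):
    scheme = sch.make_superblock_scheme(n_superblocks=4, L=2)
    return sch.build_schedule(scheme, small_geometry, L=2)


@pytest.fixture(scope="session")
def small_phantom():
    return ph.make_phantom((24, 24, 12), seed=11)


@pytest.fixture(scope="session")
def small_b0(small_phantom):
    return ph.dwi_signal(small_phantom, 0.0, np.zeros(3), 0.107)
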
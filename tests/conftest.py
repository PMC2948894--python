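import numpy as np
import pytest

from petseg.volume_io import PETVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume(rng):
    """Small random PET volume with anisotropic voxels."""
    return PETVolume(rng.random((12, 10, 4)), (4.07, 4.07, 5.0), "random test volume")


def make_volume(voxels, voxel_size=(1.0, 1.0, 1.0)):
    return PETVolume(np.asarray(voxels, dtype=float), voxel_size)
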
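import numpy as np
import pytest

from gfquant.stack_io import BinaryMask, VoxelGeometry, VoxelStack


@pytest.fixture
def cubic_geometry():
    """Isotropic 0.22 um voxels, the in-plane acquisition pitch."""
    return VoxelGeometry(dx=0.22, dy=0.22, dz=0.22)


@pytest.fixture
def stack_geometry():
    """Acquisition-like geometry: 0.22 um pixels, 1 um slices."""
    return VoxelGeometry(dx=0.22, dy=0.22, dz=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def random_stack(rng, cubic_geometry):
    def make(shape=(3, 8, 8), high=255, name="test"):
        return VoxelStack(rng.integers(0, high + 1, size=shape), cubic_geometry, name)

    return make


@pytest.fixture
def random_mask(rng, cubic_geometry):
    def make(shape=(3, 8, 8), p=0.5):
        return BinaryMask(rng.random(shape) < p, cubic_geometry)

    return make
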
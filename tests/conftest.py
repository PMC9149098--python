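import numpy as np
import pytest

from tomoperm.io import VoxelVolume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noise_volume(rng):
    """64-cubed standard-normal volume at 1 A/voxel."""
    return VoxelVolume(rng.standard_normal((64, 64, 64)), 1.0)


@pytest.fixture
def small_noise_volume(rng):
    return VoxelVolume(rng.standard_normal((32, 32, 32)), 2.62)
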
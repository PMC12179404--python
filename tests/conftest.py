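import numpy as np
import pytest

from glymphkit.io import VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def binary_mask_grid():
    """A small binary mask with non-trivial content and 1-mm spacing."""
    data = np.zeros((10, 10, 10), dtype=np.uint8)
    data[3:6, 3:6, 3:6] = 1
    return VoxelGrid.from_array(data, spacing=(1.0, 1.0, 1.0))
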
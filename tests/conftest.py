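import numpy as np
import pytest

from tofvasc.grids import BinaryMask, VolumeGrid

FLASH_SPACING = (0.117, 0.117, 0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_phantom():
    from tofvasc.synthetic import make_phantom_bundle

    return make_phantom_bundle(1, "small")


def make_volume(data, spacing=(1.0, 1.0, 1.0)):
    return VolumeGrid(np.asarray(data, dtype=np.float32), spacing)


def make_mask(data, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(np.asarray(data).astype(bool), spacing)


def y_skeleton(spacing=(1.0, 1.0, 1.0)):
    """Y-shaped skeleton: arms of 10, 8 and 6 voxels meeting at a junction.

    Arms run along +x, -x and +y from the junction at (12, 12, 2).
    Returns (mask, junction, arm voxel lists).
    """
    data = np.zeros((25, 25, 5), dtype=bool)
    j = (12, 12, 2)
    arm10 = [(12 + i, 12, 2) for i in range(1, 11)]
    arm8 = [(12 - i, 12, 2) for i in range(1, 9)]
    arm6 = [(12, 12 + i, 2) for i in range(1, 7)]
    for v in [j] + arm10 + arm8 + arm6:
        data[v] = True
    return make_mask(data, spacing), j, arm10, arm8, arm6
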
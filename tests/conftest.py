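import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from ezbattery.volumes import BinaryVolume, LabeledVolume, VolumeGrid


@pytest.fixture
def grid10():
    return VolumeGrid.isotropic((10, 10, 10), 2.0)


@pytest.fixture
def slab_grid():
    """6×6×1 slab at 2 mm: small enough to enumerate mask placements."""
    return VolumeGrid.isotropic((6, 6, 1), 2.0)


@pytest.fixture
def slab_brain(slab_grid):
    return BinaryVolume(grid=slab_grid, mask=np.ones((6, 6, 1), bool), role="brain")


@pytest.fixture
def cube_brain(grid10):
    """Full-cube brain of 1000 voxels (so the 90th percentile keeps 100)."""
    return BinaryVolume(grid=grid10, mask=np.ones((10, 10, 10), bool), role="brain")


def make_volume(grid, values, label="m", subject="s"):
    return LabeledVolume(grid=grid, values=np.asarray(values, dtype=float),
                         label=label, subject=subject)
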
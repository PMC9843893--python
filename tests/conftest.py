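import numpy as np
import pytest

from pancrad.volume import CTVolume, LabelMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume_pair(rng):
    """A 6-slice 32x32 volume with a blob ROI containing a 'tumor' core."""
    shape = (6, 32, 32)
    vox = rng.normal(80, 15, size=shape)
    labels = np.zeros(shape, dtype=np.uint8)
    z, y, x = np.ogrid[:6, :32, :32]
    blob = ((z - 3) ** 2 / 4 + (y - 16) ** 2 / 100 + (x - 16) ** 2 / 100) <= 1
    core = ((z - 3) ** 2 / 2 + (y - 16) ** 2 / 16 + (x - 16) ** 2 / 16) <= 1
    labels[blob] = 1
    labels[core] = 2
    vol = CTVolume(voxels=vox, spacing=(1.0, 1.0, 5.0))
    mask = LabelMask(labels=labels, spacing=(1.0, 1.0, 5.0))
    return vol, mask
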
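import numpy as np
import pytest

from nativecam.io_core import LabelVolume, RegionInfo, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_volume(rng):
    """A 12x12x12 volume with distinct random values and identity affine."""
    data = rng.normal(size=(12, 12, 12))
    return Volume(data=data, affine=np.eye(4), id="rand")


@pytest.fixture
def toy_labels():
    """A 6x6x6 two-region label volume on an identity grid."""
    labels = np.zeros((6, 6, 6), dtype=np.int32)
    labels[1:5, 1:5, 1:3] = 1
    labels[1:5, 1:5, 3:5] = 2
    table = {1: RegionInfo("region-a", "left"), 2: RegionInfo("region-b", "right")}
    return LabelVolume(labels=labels, affine=np.eye(4), label_table=table)
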
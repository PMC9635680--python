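import numpy as np
import pytest

from tauoi import phantom as ph
from tauoi.suvr_metrics import DEFAULT_META_REGIONS
from tauoi.volumes_io import BinaryMask, Volume3D, roi_mask


@pytest.fixture(scope="session")
def atlas_and_csf():
    return ph.default_atlas()


@pytest.fixture(scope="session")
def atlas(atlas_and_csf):
    return atlas_and_csf[0]


@pytest.fixture(scope="session")
def csf(atlas_and_csf):
    return atlas_and_csf[1]


@pytest.fixture(scope="session")
def meta_roi(atlas):
    return roi_mask(atlas, DEFAULT_META_REGIONS)


def make_volume(data, units="suvr"):
    data = np.asarray(data, dtype=float)
    return Volume3D(data, (1.0, 1.0, 1.0), np.eye(4), units=units)


def make_mask(data):
    data = np.asarray(data)
    return BinaryMask(data.astype(bool), (1.0, 1.0, 1.0), np.eye(4))


def full_roi(shape):
    return make_mask(np.ones(shape, dtype=bool))


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
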
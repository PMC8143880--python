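import numpy as np
import pytest

from lccnet.architecture import BackboneConfig
from lccnet.data_io import DataSplit, make_split
from lccnet.phantom import PhantomParams, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def micro_cfg():
    """Smallest usable backbone (for fast training tests)."""
    return BackboneConfig(depth=2, base_width=4, block_kind="ghost")


@pytest.fixture(scope="session")
def tiny_cfg():
    """The desk-scale backbone used in the phantom experiments."""
    return BackboneConfig.tiny()


@pytest.fixture(scope="session")
def micro_params():
    """Phantom geometry scaled down to 32x32 slices."""
    return PhantomParams(
        image_size=32,
        slices_per_subject=3,
        lv_radius_range=(3.0, 4.5),
        myo_thickness_range=(1.5, 2.0),
        rv_radius_range=(2.5, 4.0),
        center_jitter=1.5,
    )


@pytest.fixture(scope="session")
def micro_split(micro_params) -> DataSplit:
    """A small labeled/unlabeled/test split of 32x32 phantom subjects."""
    subjects = generate_dataset(10, micro_params, seed=7)
    return make_split(subjects, K=2, test_count=3, seed=7)
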
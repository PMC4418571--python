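import numpy as np
import pytest

from tonorep import (
    FrequencyProgression,
    SheetSpec,
    make_block_design,
    make_tonotopic_sheet,
)
from tonorep.parcellation import RoiSet


@pytest.fixture(scope="session")
def default_gt():
    """Default left-hemisphere ground-truth sheet."""
    return make_tonotopic_sheet(SheetSpec(), seed=1)


@pytest.fixture(scope="session")
def gt_rois(default_gt):
    """ROI set taken from the ground-truth labels."""
    return RoiSet(labels=default_gt.labels)


@pytest.fixture(scope="session")
def progression():
    return FrequencyProgression()


@pytest.fixture(scope="session")
def block_design():
    return make_block_design(8, tr=2.0)


@pytest.fixture(scope="session")
def small_pool():
    """Small synthetic sound pool shared across matching tests."""
    from tonorep import make_sound_pool

    return make_sound_pool(60, seed=5)
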
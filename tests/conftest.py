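import numpy as np
import pytest

from mhfaseg.synthetic import SyntheticSpec, make_lesion


@pytest.fixture(scope="session")
def lesion_phantom():
    """One 128x128 hair-free lesion phantom (image, mask)."""
    img, mask, _, _ = make_lesion(
        SyntheticSpec(kind="lesion", size=(128, 128), hair=False, seed=3), 0
    )
    return img, mask


@pytest.fixture(scope="session")
def hairy_phantom():
    """One 128x128 hairy lesion phantom (image, mask, clean, hair_truth)."""
    return make_lesion(
        SyntheticSpec(kind="lesion", size=(128, 128), hair=True, seed=3), 0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
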
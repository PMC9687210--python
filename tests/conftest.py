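import numpy as np
import pytest

import cxrnodule as cx


@pytest.fixture(scope="session")
def small_phantoms():
    """A small phantom set with nodules large/bright enough for the toy detector."""
    cfg = cx.PhantomConfig(
        n_images=12,
        seed=11,
        nodules_per_image=(1, 2),
        nodule_diameter_mm_range=(8.0, 25.0),
        nodule_contrast_range=(0.3, 0.45),
    )
    return cx.generate_phantoms(cfg)


@pytest.fixture(scope="session")
def blank_phantoms():
    """Nodule-free phantoms for response-floor calibration."""
    cfg = cx.PhantomConfig(n_images=6, seed=12, nodules_per_image=(0, 0))
    images, truths, _ = cx.generate_phantoms(cfg)
    assert not truths
    return images


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
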
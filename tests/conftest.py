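import numpy as np
import pytest

import roimosaic as rm


@pytest.fixture(scope="session")
def easy_images():
    """A small high-contrast, low-speckle phantom set (shared, read-only)."""
    params = rm.easy_params(n_benign=8, n_malignant=8, seed=3)
    return rm.generate_images(params)


@pytest.fixture(scope="session")
def layout_2x2():
    return rm.MosaicLayout.default_2x2(128, 128)


@pytest.fixture()
def tile_sized_sources(layout_2x2):
    """Four tile-sized flat images, one centered box each, 2 benign + 2 malignant."""

    def make(image_id, label, value):
        pixels = np.full((128, 128), value)
        return rm.AnnotatedImage(image_id, pixels, [rm.RoiBox(10, 10, 20, 20, label)], label)

    benign = [make("b0", "benign", 0.3), make("b1", "benign", 0.4)]
    malignant = [make("m0", "malignant", 0.5), make("m1", "malignant", 0.6)]
    return benign, malignant
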
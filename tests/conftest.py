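import numpy as np
import pytest

from marblesense import (
    BeefClass,
    DEFAULT_SPECS,
    generate_image,
    make_ellipse_mask,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def medium_mask():
    """The 960x720 medium ROI: centre (480, 360), semi-axes (360, 270)."""
    return make_ellipse_mask(960, 720, 0.75)


@pytest.fixture(scope="session")
def class_images():
    """One rendered (image, fat mask) pair per beef class, fixed seeds."""
    return {
        cls: generate_image(DEFAULT_SPECS[cls], seed=100 + int(cls))
        for cls in BeefClass
    }


@pytest.fixture(scope="session")
def random_block(rng):
    """An 80x80 random RGB block."""
    return rng.integers(0, 256, size=(80, 80, 3)).astype(np.uint8)


@pytest.fixture(scope="session")
def toy_clusters():
    """Three tight, well-separated 2-D Gaussian clusters, one per class.

    Nearest-centroid classification is a perfect oracle on this set, so any
    sane kernel classifier must reach 100% accuracy.
    """
    gen = np.random.default_rng(7)
    centers = {BeefClass.WAGYU: (0.0, 0.0),
               BeefClass.REGULAR: (1.0, 0.0),
               BeefClass.FAT_INJECTED: (0.0, 1.0)}
    X, y = [], []
    for cls, c in centers.items():
        pts = gen.normal(loc=c, scale=0.01, size=(40, 2))
        X.append(pts)
        y.extend([int(cls)] * 40)
    return np.vstack(X), np.asarray(y), centers
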
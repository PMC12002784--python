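import numpy as np
import pytest

from trusseg.volume_io import SegmentationMask, Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_volume(rng):
    """An 8x8x8 random-intensity volume with unit spacing."""
    return Volume3D(rng.random((8, 8, 8)), spacing=(1, 1, 1), origin=(0, 0, 0))


def make_ellipsoid_mask(semi_axes=(20.0, 25.0, 30.0), shape=(96, 96, 96),
                        spacing=(1.0, 1.0, 1.0)) -> SegmentationMask:
    """Rasterize an axis-aligned ellipsoid centred in the grid."""
    ax = [np.arange(n) * s for n, s in zip(shape, spacing)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    c = [(n - 1) / 2 * s for n, s in zip(shape, spacing)]
    inside = (((X - c[0]) / semi_axes[0]) ** 2
              + ((Y - c[1]) / semi_axes[1]) ** 2
              + ((Z - c[2]) / semi_axes[2]) ** 2) <= 1.0
    return SegmentationMask(inside.astype(np.uint8), spacing, (0.0, 0.0, 0.0))


def random_blob_mask(rng, shape=(16, 16, 16), p=0.5, spacing=(1.0, 1.0, 1.0)):
    """A smoothed random binary mask (blob-like, usually non-empty)."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=2.0)
    mask = field > np.quantile(field, 1 - p)
    return SegmentationMask(mask.astype(np.uint8), spacing, (0.0, 0.0, 0.0))
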
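import numpy as np
import pytest
from scipy import ndimage as ndi

from snakuscules.model import WeightProfile


@pytest.fixture(scope="session")
def profile3d():
    return WeightProfile(delta_R=4.0, ndim=3)


@pytest.fixture(scope="session")
def profile2d():
    return WeightProfile(delta_R=4.0, ndim=2)


def make_blob_image(shape=64, r0=10.0, center=(31.7, 31.4, 31.2), sigma=1.0):
    grids = np.ogrid[tuple(slice(0, shape) for _ in center)]
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    img = (r < r0).astype(np.float64)
    if sigma > 0:
        img = ndi.gaussian_filter(img, sigma)
    return img


@pytest.fixture(scope="session")
def blob_image():
    """Isolated smoothed sphere, r0=10, at a generic off-lattice center."""
    return make_blob_image()


@pytest.fixture(scope="session")
def blob_center():
    return np.array([31.7, 31.4, 31.2])


@pytest.fixture(scope="session")
def smooth_field():
    """Random smooth test image on [0, 1] (48^3)."""
    rng = np.random.default_rng(0)
    arr = ndi.gaussian_filter(rng.random((48, 48, 48)), 2.0)
    return (arr - arr.min()) / (arr.max() - arr.min())


@pytest.fixture(scope="session")
def voxelized_blob_96():
    """Sharp binary blob (intensities 0/2), r0=10 vox, 96^3 grid."""
    center = np.array([47.23, 47.61, 48.11])
    grids = np.ogrid[0:96, 0:96, 0:96]
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    return 1.0 + np.sign(10.0 - r), center
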
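import numpy as np
import pytest

from phenoprof.segmentation import SegmentationParams
from phenoprof.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A 5-cell scene with well-separated cells plus its ground truth."""
    return generate_scene(SceneSpec(seed=42, n_cells=5))


@pytest.fixture(scope="session")
def default_params():
    return SegmentationParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_label_mask(rng, shape=(24, 24), n_blobs=4):
    """A random blobby label mask for metric-oracle comparisons."""
    field = rng.normal(size=shape)
    from scipy import ndimage as ndi

    smooth = ndi.gaussian_filter(field, 2.0)
    fg = smooth > np.quantile(smooth, 0.6)
    labels, _ = ndi.label(fg)
    return labels.astype(np.int32)
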
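import numpy as np
import pytest

from foliar import synthetic


@pytest.fixture(scope="session")
def leaf_set():
    """Small 3-class leaf fixture shared across tests."""
    spec = synthetic.LeafImageSpec(classes=3, per_class=10, side=64, seed=42)
    images, labels, masks = synthetic.make_leaf_images(spec)
    return images, labels, masks


@pytest.fixture(scope="session")
def low_contrast_leaf():
    spec = synthetic.LeafImageSpec(classes=2, per_class=4, side=64, disease_contrast=0.1, seed=7)
    images, _labels, masks = synthetic.make_leaf_images(spec)
    return images[0], masks[0]


@pytest.fixture(scope="session")
def dehaze_scene():
    return synthetic.make_dehaze_scene(96, seed=5)


@pytest.fixture(scope="session")
def feature_fixture():
    """The 40-column selection fixture: 5 informative, 10 redundant, 25 noise."""
    spec = synthetic.FeatureSpec(seed=11)
    fm, signal = synthetic.make_feature_matrix(spec)
    return spec, fm, signal


def luminance(image: np.ndarray) -> np.ndarray:
    return image @ np.array([0.299, 0.587, 0.114])
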
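import numpy as np
import pytest

import stroketex as st


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noise_image():
    """A 64x64 continuous noise image, fixed seed."""
    r = np.random.default_rng(7)
    return st.GrayImage(np.clip(0.5 + 0.15 * r.standard_normal((64, 64)), 0, 1))


@pytest.fixture(scope="session")
def phantom_trio():
    """One default phantom per class at working resolution."""
    return {cls: st.make_phantom(st.default_spec(cls, seed=11)) for cls in st.CLASSES}


@pytest.fixture(scope="session")
def small_phantom_features():
    """Feature matrix of 15 phantoms/class at 64 px with a coarse HOS grid.

    Session-scoped because several classifier tests reuse it.
    """
    imgs, labels = [], []
    for ci, cls in enumerate(st.CLASSES):
        for j in range(15):
            imgs.append(st.make_phantom(st.default_spec(cls, seed=5000 + ci * 100 + j,
                                                        size=64)))
            labels.append(cls)
    X = st.extract_feature_matrix(imgs, hos_angles=range(1, 181, 30))
    return X, np.asarray(labels)
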
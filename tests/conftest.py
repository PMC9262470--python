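import numpy as np
import pytest

from orascreen.features import FeatureExtractorSpec
from orascreen.gabor import default_bank, preprocess
from orascreen.features import extract_features
from orascreen.synthetic import SyntheticConfig, make_texture_dataset


@pytest.fixture(scope="session")
def small_texture_config() -> SyntheticConfig:
    """Scaled-down texture set: 20 + 10 images at 64 x 64."""
    return SyntheticConfig(n_class_a=20, n_class_b=10, image_size=(64, 64), seed=3)


@pytest.fixture(scope="session")
def small_texture_dataset(small_texture_config):
    return make_texture_dataset(small_texture_config)


@pytest.fixture(scope="session")
def small_texture_features(small_texture_dataset):
    """Bank-preprocessed pooled-Gabor features of the small texture set."""
    images, labels, _ = small_texture_dataset
    bank = default_bank()
    spec = FeatureExtractorSpec(
        kind="pooled_gabor", output_dim=64, target_size=(64, 64), seed=11
    )
    filtered = [preprocess(img, bank) for img in images]
    X = np.vstack([extract_features(img, spec, bank) for img in filtered])
    return X, np.asarray(labels)


@pytest.fixture(scope="session")
def cluster_data():
    """Well-separated 10-D Gaussian clusters (400 points, Bayes error < 1%)."""
    from orascreen.synthetic import make_feature_clusters

    return make_feature_clusters(n_per_class=200, dim=10, separation=6.0, seed=42)
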
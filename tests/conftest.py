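import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_separable_dataset():
    """Small low-noise dataset with uninformative metadata (meta_effect=0)."""
    from metafuse.synthetic import SynthConfig, generate_dataset

    cfg = SynthConfig(n_samples=80, n_classes=2, image_size=16,
                      meta_effect=0.0, noise_sd=0.02, seed=7)
    return generate_dataset(cfg)


def dataset_arrays(samples):
    images = np.stack([s.image for s in samples]).transpose(0, 3, 1, 2) / 255.0
    records = [s.metadata for s in samples]
    labels = [s.label for s in samples]
    return images, records, labels
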
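import numpy as np
import pytest

from attnguide import AugmentationConfig, PhantomConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    return PhantomConfig(
        image_width=96,
        image_height=96,
        n_per_class={"Normal": 6, "CystTumor": 6, "LMBD": 6},
        lesion_radius_range=(5, 8),
        seed=0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    samples, manifest = generate_dataset(small_config, attention_rate=1.0, seed=0)
    return samples, manifest


@pytest.fixture
def small_aug():
    return AugmentationConfig(crop_size=(80, 80))
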
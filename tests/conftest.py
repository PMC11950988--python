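import numpy as np
import pytest

from aspectscore.phantom import (
    PhantomConfig,
    atlas_reference_images,
    build_atlas,
)


@pytest.fixture(scope="session")
def config():
    """Noise-free default-size phantom configuration."""
    return PhantomConfig(image_size=256, noise_sd=0.0)


@pytest.fixture(scope="session")
def atlas(config):
    return build_atlas(config)


@pytest.fixture(scope="session")
def ref_images(atlas, config):
    return atlas_reference_images(atlas, config)


@pytest.fixture(scope="session")
def config128():
    return PhantomConfig(image_size=128, noise_sd=0.0)


@pytest.fixture(scope="session")
def atlas128(config128):
    return build_atlas(config128)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240916)
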
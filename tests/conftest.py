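import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from leafspec.datasets import (ImageSimConfig, SpectraSimConfig,
                               generate_leaf_image, generate_spectra)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def spectra_set():
    """A moderate planted-band spectra set shared by read-only tests."""
    return generate_spectra(SpectraSimConfig(n_samples=120, seed=7))


@pytest.fixture()
def clean_image():
    """Noise-free leaf image with its ground-truth mask."""
    cfg = ImageSimConfig(pixel_noise_sd=0.0, seed=1)
    img, mask = generate_leaf_image(1.0, cfg)
    return img, mask, cfg
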
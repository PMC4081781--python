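import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ridge_image(size=64, freq=0.18, angle=0.6, amplitude=35.0, seed=0):
    """Quasi-periodic oriented ridge texture, the package's canonical test image."""
    rng = np.random.default_rng(seed)
    rows, cols = np.indices((size, size)).astype(np.float64)
    proj = cols * np.cos(angle) + rows * np.sin(angle)
    img = 128.0 + amplitude * np.cos(2 * np.pi * freq * proj)
    img += 8.0 * rng.standard_normal((size, size))
    return np.clip(img, 0.0, 255.0)


@pytest.fixture
def ridges():
    return ridge_image()
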
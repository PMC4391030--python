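import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def disc_image():
    """640x480 bright frame with a dark disc of radius 40 at (300, 200)."""
    img = np.full((480, 640), 200, dtype=np.uint8)
    ys, xs = np.mgrid[0:480, 0:640]
    disc = (xs - 300) ** 2 + (ys - 200) ** 2 <= 40**2
    img[disc] = 10
    return img, disc


def rasterize_ellipse(shape, center, axes):
    """Pixel-center rasterization ((x-h)/b)^2 + ((y-k)/a)^2 <= 1."""
    h, k = center
    a, b = axes
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    return ((xs - h) / b) ** 2 + ((ys - k) / a) ** 2 <= 1.0
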
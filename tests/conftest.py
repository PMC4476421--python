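import numpy as np
import pytest

from snsmil.camera import CameraOpticsConfig


@pytest.fixture
def camera() -> CameraOpticsConfig:
    """Benchmark optics: 64 nm pixels, 665 nm emission, NA 1.49, EMCCD."""
    return CameraOpticsConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def gaussian_spot(shape, x0, y0, amplitude, sigma, offset=0.0):
    """Noise-free 2D Gaussian image sampled at pixel centres (row=y, col=x)."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return amplitude * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2)) + offset
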
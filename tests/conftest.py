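import numpy as np
import pytest

from texsurv import ImageSlice, PhantomSpec, RoiMask, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def noiseless_phantom():
    """Homogeneous 100-HU disc, no core, no noise."""
    spec = PhantomSpec(
        grid_size=64, pixel_spacing=1.0, tumor_radius=20.0,
        rim_hu=100.0, core_fraction=0.0, noise_sd=0.0, seed=0,
    )
    return generate_phantom(spec)


@pytest.fixture
def random_slice(rng):
    return ImageSlice(rng.normal(50.0, 30.0, size=(64, 64)), spacing=1.0)


def disc_mask(shape, radius_px):
    g = shape[0]
    c = (g - 1) / 2
    yy, xx = np.mgrid[:g, :g]
    return RoiMask(np.hypot(xx - c, yy - c) <= radius_px)


def brute_force_filter(pixels, kernel):
    """Direct spatial-domain convolution with symmetric padding (oracle)."""
    r = kernel.shape[0] // 2
    padded = np.pad(pixels, r, mode="symmetric")
    out = np.zeros_like(pixels, dtype=float)
    n = pixels.shape[0]
    m = pixels.shape[1]
    for u in range(kernel.shape[0]):
        for v in range(kernel.shape[1]):
            # convolution: kernel index (u, v) pairs with the flipped offset
            out += kernel[kernel.shape[0] - 1 - u, kernel.shape[1] - 1 - v] * \
                padded[u:u + n, v:v + m]
    return out
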
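import numpy as np
import pytest

from granuleseg.io_config import GrayImage
from granuleseg.synthetic import SceneSpec, _capsule_coverage, _disc_coverage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_free_spec():
    """Scene parameters with noise, illumination and the nucleus switched off."""
    return SceneSpec(
        noise_sigma=0.0,
        illumination_gradient_amplitude=0.0,
        nucleus_present=False,
        seed=0,
    )


def render_disc(radius_px, shape=(64, 64), center=None, value=255, background=0):
    """Anti-aliased disc fixture; returns (GrayImage, boolean mask)."""
    if center is None:
        center = (shape[0] / 2, shape[1] / 2)
    cov = _disc_coverage(shape, (0, 0), center, radius_px)
    px = np.clip(background + (value - background) * cov, 0, 255).astype(np.uint8)
    return px, cov > 0.5


def render_capsule(aspect, area_px, shape=(64, 64), center=None):
    """Capsule with given aspect ratio and target area; returns boolean mask."""
    if center is None:
        center = (shape[0] / 2, shape[1] / 2)
    rho = np.sqrt(area_px / (np.pi + 4.0 * (aspect - 1.0)))
    ell = rho * (aspect - 1.0)
    p0 = (center[0], center[1] - ell)
    p1 = (center[0], center[1] + ell)
    cov = _capsule_coverage(shape, (0, 0), p0, p1, rho)
    return cov > 0.5


@pytest.fixture
def gray_from_mask():
    def _make(mask, fg=200, bg=30, pixel_size_nm=10.0):
        px = np.where(mask, fg, bg).astype(np.uint8)
        return GrayImage(px, pixel_size_nm)

    return _make
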
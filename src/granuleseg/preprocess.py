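"""Global histogram equalization, the first stage of the pipeline.

Uneven illumination is the dominant low-frequency artifact in serial-section
EM; spreading the gray-level CDF over the full 8-bit range flattens it and
standardises contrast between micrographs before the network sees them.  The
same transform is applied at training and prediction time.
"""

from __future__ import annotations

import logging

import numpy as np

from .io_config import GrayImage

log = logging.getLogger(__name__)


def equalization_lut(pixels: np.ndarray) -> np.ndarray:
    """Return the 256-entry gray-level mapping h(v) for an 8-bit raster.

    h(v) = round((cdf(v) - cdf_min) / (N - cdf_min) * 255), where cdf is the
    cumulative pixel-count function, cdf_min its smallest nonzero value and N
    the total pixel count.  The mapping is monotone non-decreasing, h = 0 at
    the darkest occupied level, and h = 255 at the brightest.
    """
    counts = np.bincount(pixels.ravel(), minlength=256)
    cdf = np.cumsum(counts)
    n = cdf[-1]
    cdf_min = cdf[np.nonzero(counts)[0][0]]
    if n == cdf_min:  # constant image: mapping is undefined
        return np.arange(256, dtype=np.uint8)
    lut = np.round((cdf - cdf_min) / float(n - cdf_min) * 255.0)
    return np.clip(lut, 0, 255).astype(np.uint8)


def equalize_histogram(img: GrayImage) -> GrayImage:
    """Equalize the global gray-level histogram of a micrograph.

    A constant image has no defined mapping and is returned unchanged with a
    logged warning.
    """
    px = img.pixels
    if px.min() == px.max():
        log.warning("constant image: histogram equalization is a no-op")
        return img
    lut = equalization_lut(px)
    return GrayImage(lut[px], img.pixel_size_nm)
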
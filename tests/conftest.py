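"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage as ndi

from gliomorph import BinaryMask, CalibratedImage


def image(arr, pixel_size=1.0, channel=""):
    return CalibratedImage(np.asarray(arr, dtype=float), pixel_size, channel)


def mask(arr, pixel_size=1.0):
    return BinaryMask(np.asarray(arr, dtype=bool), pixel_size)


def brute_circular_mean(pixels: np.ndarray, radius_px: float) -> np.ndarray:
    """Nested-loop oracle: mean over the exact clipped disc at each pixel."""
    h, w = pixels.shape
    out = np.empty((h, w))
    r2 = radius_px * radius_px
    for y in range(h):
        for x in range(w):
            total = 0.0
            count = 0
            big_r = int(np.floor(radius_px))
            for dy in range(-big_r, big_r + 1):
                for dx in range(-big_r, big_r + 1):
                    if dy * dy + dx * dx <= r2:
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w:
                            total += pixels[yy, xx]
                            count += 1
            out[y, x] = total / count
    return out


def random_blob_mask(rng: np.random.Generator, n: int = 32, sigma: float = 2.0,
                     pct: float = 70.0) -> np.ndarray:
    """Smooth random blobs: the mask class segmentation actually produces."""
    f = ndi.gaussian_filter(rng.standard_normal((n, n)), sigma)
    return f > np.percentile(f, pct)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
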
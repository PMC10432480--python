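"""Classical segmentation operators for fluorescence micrographs.

The adaptive operator at the heart of this module classifies a pixel as
foreground when its intensity is *strictly* larger than the mean
intensity of a circular window (default radius 20 µm) centred on it.
Size filters then delete connected components whose area is strictly
smaller than a micrometre threshold (25 µm² for astrocyte processes,
15 µm² for connexin puncta); components exactly at the threshold are
kept.  The window membership test uses the exact pixel-centre distance
(``dy² + dx² ≤ r_px²``), and near the image border the window is clipped
to the grid with the mean taken over in-bounds pixels only.

The soma and vessel detectors at the end of the module are pluggable:
the defaults are documented classical procedures, and any callable that
produces a mask on the same grid (for instance a trained segmentation
network) can be substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .core import BinaryMask, CalibratedImage, LabelMask, STRUCT_4, STRUCT_8, um_to_px

__all__ = [
    "gaussian_smooth",
    "local_circular_mean",
    "adaptive_local_threshold",
    "remove_small_components",
    "segment_processes",
    "segment_puncta",
    "BodyDetectorConfig",
    "detect_bodies",
    "VesselDetectorConfig",
    "segment_vessels",
]


def gaussian_smooth(image: CalibratedImage, sigma_um: float) -> CalibratedImage:
    """Gaussian smoothing with a micrometre-valued sigma.

    ``sigma_um = 0`` returns an identical copy of the input.
    """
    if sigma_um < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma_um}")
    if sigma_um == 0:
        return image.like(image.pixels.copy())
    sigma_px = um_to_px(sigma_um, image.pixel_size)
    return image.like(ndi.gaussian_filter(image.pixels, sigma_px, mode="nearest"))


def _row_window_sum(arr: np.ndarray, half_width: int) -> np.ndarray:
    """Sliding sum over columns ``[j - w, j + w]`` clipped to the grid."""
    h, w = arr.shape
    c = np.zeros((h, w + 1), dtype=np.float64)
    np.cumsum(arr, axis=1, out=c[:, 1:])
    j = np.arange(w)
    hi = np.minimum(j + half_width + 1, w)
    lo = np.maximum(j - half_width, 0)
    return c[:, hi] - c[:, lo]


def local_circular_mean(image: CalibratedImage, radius_um: float) -> CalibratedImage:
    """Mean over the exact discrete disc of radius ``radius_um``.

    A pixel belongs to the window of the centre pixel iff the Euclidean
    distance between the two pixel centres is at most the radius
    converted to pixels.  Near the border the disc is clipped to the
    grid.  The disc is decomposed into row chords, each evaluated with a
    cumulative-sum sliding window, so the result matches a nested-loop
    enumeration of the disc to floating-point accuracy.
    """
    if not (radius_um > 0):
        raise ValueError(f"radius must be positive, got {radius_um}")
    r = um_to_px(radius_um, image.pixel_size)
    if r < 1.0:
        raise ValueError(
            f"window radius {radius_um} um is smaller than one pixel "
            f"({image.pixel_size} um)"
        )
    h, w = image.shape
    big_r = int(math.floor(r))
    num = np.zeros((h, w), dtype=np.float64)
    den = np.zeros((h, w), dtype=np.float64)
    ones = np.ones((h, w), dtype=np.float64)
    for dy in range(-big_r, big_r + 1):
        chord = int(math.floor(math.sqrt(max(r * r - dy * dy, 0.0))))
        src_lo, src_hi = max(0, dy), min(h, h + dy)
        dst_lo, dst_hi = max(0, -dy), min(h, h - dy)
        if src_lo >= src_hi:
            continue
        num[dst_lo:dst_hi] += _row_window_sum(image.pixels[src_lo:src_hi], chord)
        den[dst_lo:dst_hi] += _row_window_sum(ones[src_lo:src_hi], chord)
    return image.like(num / den)


def adaptive_local_threshold(
    image: CalibratedImage, radius_um: float = 20.0
) -> BinaryMask:
    """Foreground where the pixel is strictly above its circular-window mean.

    Intensities are anchored at the first pixel's value before the mean
    is taken (the strict comparison is unchanged mathematically), so
    constant regions sum to exactly zero and never leak into the
    foreground through floating-point residue.
    """
    anchored = image.like(image.pixels - image.pixels[0, 0])
    mean = local_circular_mean(anchored, radius_um)
    return BinaryMask(anchored.pixels > mean.pixels, image.pixel_size)


def remove_small_components(
    mask: BinaryMask, min_area_um2: float, connectivity: int = 8
) -> BinaryMask:
    """Delete components strictly smaller than ``min_area_um2``.

    Components whose area equals the threshold exactly are kept.
    """
    if min_area_um2 < 0:
        raise ValueError("min_area must be non-negative")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = STRUCT_8 if connectivity == 8 else STRUCT_4
    labels, n = ndi.label(mask.pixels, structure=structure)
    if n == 0:
        return mask.like(mask.pixels.copy())
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    areas = counts * mask.pixel_size**2
    # tiny epsilon guards representation error in the pixel-area product;
    # exact-threshold components must survive ("smaller than" semantics)
    keep = areas >= min_area_um2 - 1e-9
    keep[0] = False
    return mask.like(keep[labels])


def segment_processes(
    image: CalibratedImage,
    bodies: LabelMask,
    smooth_sigma_um: float = 1.0,
    window_um: float = 20.0,
    min_area_um2: float = 25.0,
) -> BinaryMask:
    """Segment astrocyte processes and union in the detected bodies.

    Pipeline: Gaussian smoothing -> strict circular-window adaptive
    threshold -> removal of components below ``min_area_um2`` -> union
    with the body mask, in that order (the size filter runs before the
    body union).
    """
    if bodies.shape != image.shape:
        raise ValueError("body mask grid does not match the image grid")
    sm = gaussian_smooth(image, smooth_sigma_um)
    fg = adaptive_local_threshold(sm, window_um)
    fg = remove_small_components(fg, min_area_um2)
    return BinaryMask(fg.pixels | (bodies.pixels > 0), image.pixel_size)


def segment_puncta(
    image: CalibratedImage,
    window_um: float = 20.0,
    min_area_um2: float = 15.0,
    smooth_sigma_um: float = 1.0,
) -> BinaryMask:
    """Segment punctate connexin signal.

    Gaussian blur, strict adaptive threshold against the 20 µm circular
    window mean, then removal of components smaller than 15 µm².
    """
    sm = gaussian_smooth(image, smooth_sigma_um)
    fg = adaptive_local_threshold(sm, window_um)
    return remove_small_components(fg, min_area_um2)


# ---------------------------------------------------------------------------
# Pluggable object detectors (classical defaults standing in for trained
# segmentation networks; any callable with the same signature can be used).
# ---------------------------------------------------------------------------


@dataclass
class BodyDetectorConfig:
    """Configuration of the default classical soma detector.

    smooth_sigma_um
        Pre-smoothing sigma.
    window_um
        Radius of the adaptive-threshold window.
    opening_radius_um
        Radius of the binary opening that erases thin processes while
        preserving compact somata.
    min_area_um2
        Minimum object area kept.
    peak_min_distance_um
        Minimum distance between distance-transform peaks used to split
        touching somata.
    max_hole_area_um2
        Fill enclosed background holes smaller than this before the
        opening (for ring-like soma stains with dim centres).  0
        disables filling; the default, because filling also closes
        regions enclosed by processes, which then masquerade as somata.
    """

    smooth_sigma_um: float = 1.0
    window_um: float = 20.0
    opening_radius_um: float = 3.0
    min_area_um2: float = 50.0
    peak_min_distance_um: float = 6.0
    max_hole_area_um2: float = 0.0


BodyDetector = Callable[[CalibratedImage, "BodyDetectorConfig"], LabelMask]


def _fill_small_holes(mask: np.ndarray, max_area_px: float) -> np.ndarray:
    filled = ndi.binary_fill_holes(mask)
    holes = filled & ~mask
    labels, n = ndi.label(holes)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes < max_area_px
    keep[0] = False
    return mask | keep[labels]


def detect_bodies(
    image: CalibratedImage,
    config: Optional[BodyDetectorConfig] = None,
    detector: Optional[BodyDetector] = None,
) -> LabelMask:
    """Detect astrocyte somata as a label mask.

    The default classical detector combines a global (Otsu) and a local
    (circular-window) threshold, fills holes, removes thin structures by
    binary opening, and splits touching blobs by watershed on the
    interior distance transform.  Supplying ``detector`` replaces the
    whole procedure, so a trained model can be plugged in.
    """
    config = config or BodyDetectorConfig()
    if detector is not None:
        out = detector(image, config)
        if out.shape != image.shape:
            raise ValueError("external detector returned a mask on a different grid")
        return out

    px = image.pixels
    if np.ptp(px) == 0:  # flat image: nothing to threshold
        return LabelMask(np.zeros(image.shape, dtype=np.int32), image.pixel_size)
    sm = gaussian_smooth(image, config.smooth_sigma_um)
    local_fg = adaptive_local_threshold(sm, config.window_um)
    mask = local_fg.pixels & (sm.pixels > threshold_otsu(sm.pixels))
    if config.max_hole_area_um2 > 0:
        mask = _fill_small_holes(
            mask, config.max_hole_area_um2 / image.pixel_size**2
        )
    open_r = max(1, round(um_to_px(config.opening_radius_um, image.pixel_size)))
    mask = ndi.binary_opening(mask, structure=disk(open_r))
    if not mask.any():
        return LabelMask(np.zeros(image.shape, dtype=np.int32), image.pixel_size)

    edt = ndi.distance_transform_edt(mask)
    min_dist = max(1, round(um_to_px(config.peak_min_distance_um, image.pixel_size)))
    peaks = peak_local_max(edt, min_distance=min_dist, labels=mask, exclude_border=False)
    markers = np.zeros(image.shape, dtype=np.int32)
    for i, (y, x) in enumerate(peaks, start=1):
        markers[y, x] = i
    if markers.max() == 0:
        labels, _ = ndi.label(mask, structure=STRUCT_8)
    else:
        labels = watershed(-edt, markers, mask=mask)
    out = LabelMask(labels.astype(np.int32), image.pixel_size)
    keep = out.table[out.table.area_um2 >= config.min_area_um2 - 1e-9]
    return _relabel_by_position(out, keep["label"].to_numpy())


def _relabel_by_position(mask: LabelMask, keep_labels: np.ndarray) -> LabelMask:
    """Relabel 1..n ordered by centroid (row-major) for determinism."""
    tab = mask.table[mask.table.label.isin(keep_labels)]
    tab = tab.sort_values(["centroid_y_um", "centroid_x_um"], kind="mergesort")
    mapping = np.zeros(int(mask.pixels.max()) + 1, dtype=np.int32)
    for new, old in enumerate(tab.label.to_numpy(), start=1):
        mapping[int(old)] = new
    return LabelMask(mapping[mask.pixels], mask.pixel_size)


@dataclass
class VesselDetectorConfig:
    """Configuration of the default classical vessel segmenter."""

    smooth_sigma_um: float = 1.0
    window_um: float = 20.0
    closing_radius_um: float = 2.0
    min_area_um2: float = 50.0


VesselDetector = Callable[[CalibratedImage, "VesselDetectorConfig"], BinaryMask]


def segment_vessels(
    image: CalibratedImage,
    config: Optional[VesselDetectorConfig] = None,
    detector: Optional[VesselDetector] = None,
) -> BinaryMask:
    """Segment the vessel network as a binary mask.

    Default classical procedure: Gaussian smoothing, strict adaptive
    threshold at the 20 µm window, morphological closing to bridge small
    gaps, and removal of components below ``min_area_um2``.  The
    adaptive threshold is mean-relative, so the result is invariant
    under adding a constant offset to the image.
    """
    config = config or VesselDetectorConfig()
    if detector is not None:
        out = detector(image, config)
        if out.shape != image.shape:
            raise ValueError("external detector returned a mask on a different grid")
        return out
    if np.ptp(image.pixels) == 0:
        return BinaryMask(np.zeros(image.shape, dtype=bool), image.pixel_size)
    sm = gaussian_smooth(image, config.smooth_sigma_um)
    mask = adaptive_local_threshold(sm, config.window_um)
    close_r = max(1, round(um_to_px(config.closing_radius_um, image.pixel_size)))
    closed = ndi.binary_closing(mask.pixels, structure=disk(close_r))
    return remove_small_components(
        BinaryMask(closed, image.pixel_size), config.min_area_um2
    )
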
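"""Calibrated raster containers shared by every stage of the pipeline.

All images and masks live on an isotropic pixel grid with a single
``pixel_size`` calibration in micrometres per pixel.  Coordinates are
0-based and row-major; the centre of pixel ``(i, j)`` sits at
``((i + 0.5) * pixel_size, (j + 0.5) * pixel_size)`` micrometres.  Every
micrometre-valued parameter (window radii, size thresholds, pruning
lengths) is converted through ``pixel_size`` exactly once, without
rounding the distance test itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "CalibratedImage",
    "BinaryMask",
    "LabelMask",
    "um_to_px",
    "px_to_um",
    "pixel_area_um2",
    "STRUCT_8",
    "STRUCT_4",
]

#: 8-connectivity structuring element (the default for every component
#: operation in this package; matches the 8-neighbour skeleton semantics).
STRUCT_8 = np.ones((3, 3), dtype=bool)
#: 4-connectivity structuring element.
STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def um_to_px(value_um: float, pixel_size: float) -> float:
    """Convert a micrometre length to (fractional) pixels."""
    return float(value_um) / float(pixel_size)


def px_to_um(value_px: float, pixel_size: float) -> float:
    """Convert a pixel length to micrometres."""
    return float(value_px) * float(pixel_size)


def pixel_area_um2(pixel_size: float) -> float:
    """Area of one pixel in square micrometres."""
    return float(pixel_size) ** 2


def _check_grid(pixels: np.ndarray, pixel_size: float) -> None:
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError("expected a non-empty 2D grid")
    if not (float(pixel_size) > 0):
        raise ValueError(f"pixel_size must be positive, got {pixel_size!r}")


@dataclass
class CalibratedImage:
    """A 2D intensity grid with a micrometre-per-pixel calibration.

    Parameters
    ----------
    pixels
        2D array of finite intensities (any float/int dtype; converted to
        float64).
    pixel_size
        Isotropic calibration in micrometres per pixel.
    channel
        Free-text channel label (e.g. ``"astrocyte"``).
    """

    pixels: np.ndarray
    pixel_size: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        _check_grid(self.pixels, self.pixel_size)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        self.pixel_size = float(self.pixel_size)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def field_area_um2(self) -> float:
        return self.pixels.size * pixel_area_um2(self.pixel_size)

    def like(self, pixels: np.ndarray) -> "CalibratedImage":
        """A new image on the same grid and calibration."""
        return CalibratedImage(pixels, self.pixel_size, self.channel)


@dataclass
class BinaryMask:
    """A boolean grid sharing the calibration of its source image."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        _check_grid(self.pixels, self.pixel_size)
        self.pixel_size = float(self.pixel_size)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_um2(self) -> float:
        """Total foreground area in square micrometres."""
        return float(self.pixels.sum()) * pixel_area_um2(self.pixel_size)

    def like(self, pixels: np.ndarray) -> "BinaryMask":
        return BinaryMask(pixels, self.pixel_size)


@dataclass
class LabelMask:
    """Connected objects on a calibrated grid.

    ``pixels`` holds non-negative integer labels (0 = background).  The
    object ``table`` is derived from the pixels and carries one row per
    label: ``label``, ``area_um2`` and the centroid in micrometres
    (pixel-centre convention).
    """

    pixels: np.ndarray
    pixel_size: float
    table: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValueError("label mask must have an integer dtype")
        _check_grid(self.pixels, self.pixel_size)
        if self.pixels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.pixel_size = float(self.pixel_size)
        if self.table is None:
            self.table = self._build_table()

    def _build_table(self) -> pd.DataFrame:
        labels = np.unique(self.pixels)
        labels = labels[labels > 0]
        rows = []
        if labels.size:
            areas = ndi.sum_labels(
                np.ones_like(self.pixels, dtype=np.float64), self.pixels, labels
            )
            centroids = ndi.center_of_mass(
                np.ones_like(self.pixels, dtype=np.float64), self.pixels, labels
            )
            for lab, area, (cy, cx) in zip(labels, areas, centroids):
                rows.append(
                    {
                        "label": int(lab),
                        "area_um2": float(area) * pixel_area_um2(self.pixel_size),
                        "centroid_y_um": (float(cy) + 0.5) * self.pixel_size,
                        "centroid_x_um": (float(cx) + 0.5) * self.pixel_size,
                    }
                )
        return pd.DataFrame(
            rows, columns=["label", "area_um2", "centroid_y_um", "centroid_x_um"]
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_objects(self) -> int:
        return len(self.table)

    def as_binary(self) -> BinaryMask:
        return BinaryMask(self.pixels > 0, self.pixel_size)
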
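"""TIFF/CSV/JSON formats and run configuration.

Images are single-plane grayscale TIFFs; integer intensities are
rescaled to [0, 1] by the dtype range, float images are taken as-is.
Calibration (µm/pixel) is supplied by the caller (config or CLI flag).
Masks are written as 8-bit TIFF (0/255).  All thresholds default to the
values of the underlying quantification protocol and are echoed into a
provenance JSON so no parameter that affects a reported number stays
hidden.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import BinaryMask, CalibratedImage, LabelMask

__all__ = [
    "load_image",
    "save_mask",
    "load_mask",
    "load_surface",
    "RunConfig",
    "write_provenance",
]


def load_image(path, pixel_size_um: float, channel: str = "") -> CalibratedImage:
    """Read a single-plane grayscale TIFF as a calibrated [0, 1] image."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    arr = tifffile.imread(path)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single grayscale plane, got shape {arr.shape} "
            "(multi-plane or RGB input is not supported)"
        )
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        arr = arr.astype(np.float64) / float(info.max)
    else:
        arr = arr.astype(np.float64)
    return CalibratedImage(arr, pixel_size_um, channel)


def save_mask(mask: BinaryMask, path) -> None:
    """Write a binary mask as 8-bit TIFF (0/255)."""
    tifffile.imwrite(Path(path), (mask.pixels.astype(np.uint8) * 255))


def load_mask(path, pixel_size_um: float) -> BinaryMask:
    arr = tifffile.imread(Path(path))
    return BinaryMask(arr > 0, pixel_size_um)


def load_surface(path) -> np.ndarray:
    """Read a surface polyline from a 2-column CSV (y_um, x_um) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return np.asarray(json.loads(path.read_text()), dtype=float)
    df = pd.read_csv(path)
    cols = [c for c in ("y_um", "x_um") if c in df.columns]
    if len(cols) == 2:
        return df[cols].to_numpy(dtype=float)
    return df.iloc[:, :2].to_numpy(dtype=float)


@dataclass
class RunConfig:
    """Everything that affects a number in the report.

    Threshold defaults are the protocol's stated values: 20 µm adaptive
    window, 25/15 µm² minimum component areas (processes/connexin), 4 µm
    spur pruning, 4.5 µm orientation window, LoG scales 4.5-9 µm with
    response threshold 0.1, 50 µm depth bins, 6 µm connexin-to-vessel
    distance, 4.5 µm diameter split, 1 µm radial annuli.
    """

    pixel_size_um: float = 1.0
    sample_id: str = "sample"
    out_dir: str = "gliomorph_out"
    # input channels (any subset)
    astrocyte_path: Optional[str] = None
    vessel_path: Optional[str] = None
    puncta_path: Optional[str] = None
    neuron_path: Optional[str] = None
    surface_path: Optional[str] = None
    # segmentation
    smooth_sigma_um: float = 1.0
    window_um: float = 20.0
    process_min_area_um2: float = 25.0
    puncta_min_area_um2: float = 15.0
    body_opening_radius_um: float = 3.0
    body_min_area_um2: float = 50.0
    body_peak_min_distance_um: float = 6.0
    body_max_hole_area_um2: float = 0.0
    vessel_closing_radius_um: float = 2.0
    vessel_min_area_um2: float = 50.0
    # skeleton / morphometrics
    prune_um: float = 4.0
    orientation_radius_um: float = 4.5
    n_orientation_bins: int = 18
    # neurons
    log_sigma_min_um: float = 4.5
    log_sigma_max_um: float = 9.0
    log_threshold: float = 0.1
    log_n_scales: int = 8
    depth_bin_um: float = 50.0
    # gliovascular
    connexin_max_dist_um: float = 6.0
    diameter_split_um: float = 4.5
    radial_step_um: float = 1.0
    radial_max_dist_um: Optional[float] = 15.0
    seed: int = 0

    def validate(self) -> None:
        positive = [
            "pixel_size_um", "window_um", "orientation_radius_um",
            "log_sigma_min_um", "log_sigma_max_um", "depth_bin_um",
            "connexin_max_dist_um", "diameter_split_um", "radial_step_um",
        ]
        for name in positive:
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        for name in ("process_min_area_um2", "puncta_min_area_um2", "prune_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.log_sigma_min_um > self.log_sigma_max_um:
            raise ValueError("log_sigma_min_um must not exceed log_sigma_max_um")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_provenance(config: RunConfig, path, extra: Optional[dict] = None) -> None:
    """Record every applied parameter (plus package version) as JSON."""
    from . import __version__

    payload = {"gliomorph_version": __version__, "config": config.to_dict()}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
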
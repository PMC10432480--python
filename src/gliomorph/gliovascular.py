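"""Astrocyte-vessel relationship metrics.

Three quantities relate the segmented compartments: (i) the fraction of
astrocytes with at least one process pixel overlapping the vessel mask;
(ii) radial density profiles of cell bodies and astrocyte signal in
1 µm annuli of distance from the vessel wall, each normalized by the
whole-sample density; (iii) connexin coverage of vessels, where
connexin pixels within 6 µm (boundary included) of the vessel mask
count as vessel-associated and are stratified by the local diameter of
the nearest vessel (<= 4.5 µm vs > 4.5 µm).

Distance "from the vessel wall" is the Euclidean distance transform of
the vessel mask (zero on the mask itself); pixels inside vessels are
excluded from annuli.  A connexin pixel's stratum is that of its
nearest vessel pixel, whose calibre is read from the nearest skeleton
pixel — so the two strata exactly partition the vessel mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import BinaryMask, LabelMask
from .vasculature import VesselMap

__all__ = [
    "fraction_contacting",
    "RadialProfile",
    "radial_profile",
    "CoverageReport",
    "connexin_coverage",
    "vessel_diameter_partition",
]

_DIST_EPS = 1e-9  # guards float representation at exact boundary distances


def fraction_contacting(
    cell_masks: LabelMask, vessel_mask: BinaryMask
) -> Optional[float]:
    """Fraction of astrocytes with >= 1 pixel overlapping the vessel mask.

    ``cell_masks`` labels every pixel belonging to a cell (processes and
    body) with that cell's id.  Returns ``None`` when there are no
    cells.
    """
    if cell_masks.shape != vessel_mask.shape:
        raise ValueError("masks are not co-registered")
    n = cell_masks.n_objects
    if n == 0:
        return None
    overlapping = np.unique(cell_masks.pixels[vessel_mask.pixels])
    k = int((overlapping > 0).sum())
    return k / n


@dataclass
class RadialProfile:
    """Densities in 1 µm annuli of distance from the vessel wall."""

    edges_um: np.ndarray
    raw_density: np.ndarray  # objects (or signal area) per µm² of annulus
    normalized: np.ndarray  # raw / whole-sample density
    annulus_area_um2: np.ndarray
    quantity: str  # "bodies" or "signal"

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dist_min_um": self.edges_um[:-1],
                "dist_max_um": self.edges_um[1:],
                "annulus_area_um2": self.annulus_area_um2,
                "raw_density": self.raw_density,
                "normalized_density": self.normalized,
                "quantity": self.quantity,
            }
        )


def radial_profile(
    vessel_mask: BinaryMask,
    bodies: Optional[LabelMask] = None,
    signal_mask: Optional[BinaryMask] = None,
    max_dist_um: Optional[float] = None,
    step_um: float = 1.0,
) -> RadialProfile:
    """Radial body-count or signal-area density from the vessel wall.

    Exactly one of ``bodies`` / ``signal_mask`` must be given.  Annulus
    ``k`` collects non-vessel pixels at EDT distance in
    ``[k*step, (k+1)*step)``; densities are normalized by the overall
    density over the whole non-vessel field, so a uniformly distributed
    quantity profiles flat at 1.
    """
    if (bodies is None) == (signal_mask is None):
        raise ValueError("provide exactly one of bodies or signal_mask")
    if not vessel_mask.pixels.any():
        raise ValueError("vessel mask is empty")
    ps = vessel_mask.pixel_size
    if max_dist_um is not None and max_dist_um < step_um:
        raise ValueError("max_dist must be at least one step")

    edt_um = ndi.distance_transform_edt(~vessel_mask.pixels) * ps
    outside = ~vessel_mask.pixels
    if max_dist_um is None:
        max_dist_um = float(np.ceil(edt_um[outside].max() / step_um) * step_um)
    n_bins = int(np.ceil(max_dist_um / step_um))
    edges = np.arange(n_bins + 1) * step_um

    bin_of = np.floor(edt_um / step_um).astype(int)
    valid = outside & (bin_of < n_bins)
    areas = np.bincount(bin_of[valid], minlength=n_bins).astype(float) * ps**2
    field_area = float(outside.sum()) * ps**2

    if bodies is not None:
        if bodies.shape != vessel_mask.shape:
            raise ValueError("masks are not co-registered")
        cy = np.round(bodies.table["centroid_y_um"].to_numpy() / ps - 0.5).astype(int)
        cx = np.round(bodies.table["centroid_x_um"].to_numpy() / ps - 0.5).astype(int)
        h, w = vessel_mask.shape
        cy = np.clip(cy, 0, h - 1)
        cx = np.clip(cx, 0, w - 1)
        dists = edt_um[cy, cx]
        inside_vessel = ~outside[cy, cx]
        counts = np.histogram(dists[~inside_vessel], bins=edges)[0].astype(float)
        total = float((~inside_vessel).sum())
        quantity = "bodies"
    else:
        if signal_mask.shape != vessel_mask.shape:
            raise ValueError("masks are not co-registered")
        sig = signal_mask.pixels & outside
        counts = (
            np.bincount(bin_of[sig & (bin_of < n_bins)], minlength=n_bins).astype(float)
            * ps**2
        )
        total = float(sig.sum()) * ps**2
        quantity = "signal"

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(areas > 0, counts / areas, 0.0)
    overall = total / field_area if field_area > 0 else np.nan
    normalized = raw / overall if overall and overall > 0 else np.full_like(raw, np.nan)
    return RadialProfile(edges, raw, normalized, areas, quantity)


def vessel_diameter_partition(
    vessel_map: VesselMap, diameter_split_um: float = 4.5
) -> np.ndarray:
    """Partition the vessel mask into calibre strata.

    Returns an int8 grid: 0 outside vessels, 1 where the nearest
    skeleton pixel has local diameter <= the split, 2 where it is
    larger.  Defined via nearest-skeleton-pixel lookup so the two
    strata exactly partition the mask.
    """
    skel = vessel_map.skeleton.pixels
    if not skel.any():
        raise ValueError("vessel map has an empty skeleton")
    small_skel = skel & (2.0 * vessel_map.radius_um <= diameter_split_um + _DIST_EPS)
    large_skel = skel & ~small_skel
    # nearest-set comparison via two distance transforms (ties favour the
    # small stratum): deterministic and exactly equivariant to grid
    # rotations, unlike nearest-index lookups with raster tie-breaking
    d_small = _dist_to_set(small_skel)
    d_large = _dist_to_set(large_skel)
    strata = np.zeros(skel.shape, dtype=np.int8)
    small = d_small <= d_large
    strata[vessel_map.mask.pixels & small] = 1
    strata[vessel_map.mask.pixels & ~small] = 2
    return strata


def _dist_to_set(target: np.ndarray) -> np.ndarray:
    """EDT to a pixel set; infinite when the set is empty."""
    if not target.any():
        return np.full(target.shape, np.inf)
    return ndi.distance_transform_edt(~target)


@dataclass
class CoverageReport:
    """Connexin coverage of vessels, stratified by local calibre."""

    coverage_small: float  # diameter <= split
    coverage_large: float  # diameter > split
    overlap_area_small_um2: float
    overlap_area_large_um2: float
    vessel_area_small_um2: float
    vessel_area_large_um2: float
    total_overlap_area_um2: float
    flagged_over_unity: bool

    def as_dict(self) -> dict:
        return dict(vars(self))


def connexin_coverage(
    puncta_mask: BinaryMask,
    vessel_map: VesselMap,
    max_dist_um: float = 6.0,
    diameter_split_um: float = 4.5,
) -> CoverageReport:
    """Connexin area within 6 µm of vessels, per vessel-calibre stratum.

    A connexin pixel with EDT distance to the vessel mask equal to or
    smaller than ``max_dist_um`` counts as vessel-associated; it is
    assigned to the stratum of its nearest vessel pixel.  Coverage of a
    stratum is the associated connexin area divided by that stratum's
    vessel area.
    """
    vmask = vessel_map.mask
    if puncta_mask.shape != vmask.shape:
        raise ValueError("masks are not co-registered")
    if not vmask.pixels.any():
        raise ValueError("vessel mask is empty")
    ps = vmask.pixel_size

    edt_um = ndi.distance_transform_edt(~vmask.pixels) * ps
    near = puncta_mask.pixels & (edt_um <= max_dist_um + _DIST_EPS)

    strata = vessel_diameter_partition(vessel_map, diameter_split_um)
    # assign each connexin pixel to the stratum of its nearest vessel
    # pixel, again via nearest-set distances with ties to small
    d_small = _dist_to_set(strata == 1)
    d_large = _dist_to_set(strata == 2)
    stratum_of_nearest = np.where(d_small <= d_large, 1, 2).astype(np.int8)

    area_px = ps**2
    overlap_small = float(((stratum_of_nearest == 1) & near).sum()) * area_px
    overlap_large = float(((stratum_of_nearest == 2) & near).sum()) * area_px
    vessel_small = float((strata == 1).sum()) * area_px
    vessel_large = float((strata == 2).sum()) * area_px

    cov_small = overlap_small / vessel_small if vessel_small > 0 else 0.0
    cov_large = overlap_large / vessel_large if vessel_large > 0 else 0.0
    return CoverageReport(
        coverage_small=cov_small,
        coverage_large=cov_large,
        overlap_area_small_um2=overlap_small,
        overlap_area_large_um2=overlap_large,
        vessel_area_small_um2=vessel_small,
        vessel_area_large_um2=vessel_large,
        total_overlap_area_um2=overlap_small + overlap_large,
        flagged_over_unity=(cov_small > 1.0) or (cov_large > 1.0),
    )
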
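"""Per-sample astrocyte morphometrics.

Densities are reported on the scales the field uses: cells and branch
points per mm², extension length in µm of medial line per µm² of
sample.  The process-angle entropy is the Shannon entropy (base 2) of
the histogram of local medial-line orientations of one astrocyte; a
sample's value is the mean over its astrocytes.  Local orientation at a
skeleton pixel is the principal axis (total least squares) of all
medial-line points of the same skeleton that are geodesically reachable
within a Euclidean window (default 4.5 µm) of the reference pixel —
geodesic reachability prevents borrowing points from a nearby unrelated
process.  Orientations are undirected angles in [0, pi).

Defaults that the method itself leaves open: 18 orientation bins of 10°
over [0, pi), entropy in bits, angles unweighted by segment length.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core import LabelMask
from .skeleton import CellGraph, Skeleton, skeleton_total_length

__all__ = [
    "astrocyte_density",
    "extension_length_density",
    "branching_density",
    "local_orientation",
    "skeleton_orientations",
    "angle_entropy",
    "CellRecord",
    "SampleReport",
]

UM2_PER_MM2 = 1.0e6


def astrocyte_density(bodies: LabelMask, area_um2: float) -> float:
    """Astrocytes per mm²: object count divided by the sample area."""
    if not (area_um2 > 0):
        raise ValueError("sample area must be positive")
    return bodies.n_objects / area_um2 * UM2_PER_MM2


def extension_length_density(
    skeletons: Iterable[Skeleton], area_um2: float
) -> float:
    """Summed medial-line arc length divided by the sample area (µm/µm²)."""
    if not (area_um2 > 0):
        raise ValueError("sample area must be positive")
    return sum(skeleton_total_length(s) for s in skeletons) / area_um2


def branching_density(graphs: Iterable[CellGraph], area_um2: float) -> float:
    """Branch points (graph nodes of degree >= 3) per mm²."""
    if not (area_um2 > 0):
        raise ValueError("sample area must be positive")
    return sum(g.n_branch_points for g in graphs) / area_um2 * UM2_PER_MM2


# ---------------------------------------------------------------------------
# Orientation and entropy
# ---------------------------------------------------------------------------


def _principal_angle(points: np.ndarray) -> float:
    """Total-least-squares orientation of a point set, in [0, pi).

    The principal axis of the centred second-moment matrix; vertical
    point sets are not degenerate.  Angle measured from the +x (column)
    axis.
    """
    pts = points - points.mean(axis=0)
    cyy = float(np.dot(pts[:, 0], pts[:, 0]))
    cxx = float(np.dot(pts[:, 1], pts[:, 1]))
    cxy = float(np.dot(pts[:, 0], pts[:, 1]))
    ang = 0.5 * math.atan2(2.0 * cxy, cxx - cyy)
    return ang % math.pi


def _window_points(
    coords: np.ndarray,
    adjacency: list[list[int]],
    start: int,
    radius_px: float,
) -> np.ndarray:
    """Geodesic BFS restricted to the Euclidean ball around ``start``."""
    r2 = radius_px * radius_px
    y0, x0 = coords[start]
    seen = {start}
    queue = deque([start])
    keep = [start]
    while queue:
        i = queue.popleft()
        for j in adjacency[i]:
            if j in seen:
                continue
            dy = coords[j, 0] - y0
            dx = coords[j, 1] - x0
            if dy * dy + dx * dx < r2:
                seen.add(j)
                keep.append(j)
                queue.append(j)
    return coords[keep]


def _build_adjacency(coords: np.ndarray) -> list[list[int]]:
    index = {(int(y), int(x)): i for i, (y, x) in enumerate(coords)}
    adjacency: list[list[int]] = []
    for y, x in coords:
        nbrs = []
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == 0 and dx == 0:
                    continue
                j = index.get((int(y) + dy, int(x) + dx))
                if j is not None:
                    nbrs.append(j)
        adjacency.append(nbrs)
    return adjacency


def skeleton_orientations(
    skeleton: Skeleton, radius_um: float = 4.5
) -> np.ndarray:
    """Local orientation at every skeleton pixel (radians in [0, pi)).

    Pixels whose window holds fewer than two points are skipped.
    """
    coords = np.argwhere(skeleton.pixels)
    if coords.size == 0:
        return np.empty(0)
    radius_px = radius_um / skeleton.pixel_size
    adjacency = _build_adjacency(coords)
    out = []
    for i in range(len(coords)):
        pts = _window_points(coords, adjacency, i, radius_px)
        if len(pts) >= 2:
            out.append(_principal_angle(pts.astype(np.float64)))
    return np.asarray(out)


def local_orientation(
    skeleton: Skeleton, reference_pixel: tuple[int, int], radius_um: float = 4.5
) -> Optional[float]:
    """Orientation at one reference pixel, or ``None`` if undefined."""
    coords = np.argwhere(skeleton.pixels)
    matches = np.flatnonzero(
        (coords[:, 0] == reference_pixel[0]) & (coords[:, 1] == reference_pixel[1])
    )
    if matches.size == 0:
        raise ValueError(f"reference pixel {reference_pixel} is not on the skeleton")
    adjacency = _build_adjacency(coords)
    pts = _window_points(
        coords, adjacency, int(matches[0]), radius_um / skeleton.pixel_size
    )
    if len(pts) < 2:
        return None
    return _principal_angle(pts.astype(np.float64))


def angle_entropy(angles: np.ndarray, n_bins: int = 18) -> Optional[float]:
    """Shannon entropy (bits) of the orientation histogram over [0, pi).

    Returns ``None`` when no orientation is defined; the caller is
    expected to exclude such cells with a logged warning.
    """
    angles = np.asarray(angles, dtype=np.float64)
    if angles.size == 0:
        return None
    hist, _ = np.histogram(angles % math.pi, bins=n_bins, range=(0.0, math.pi))
    p = hist[hist > 0] / angles.size
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# Report containers
# ---------------------------------------------------------------------------


@dataclass
class CellRecord:
    """Per-astrocyte summary row."""

    cell_id: int
    n_branch_points: int
    n_terminations: int
    total_length_um: float
    angle_entropy_bits: Optional[float]
    contacts_vessel: Optional[bool] = None


@dataclass
class SampleReport:
    """Per-sample astrocyte morphometry."""

    sample_id: str
    area_um2: float
    astrocyte_density_mm2: float
    extension_length_density: float
    branching_density_mm2: float
    mean_angle_entropy_bits: Optional[float]
    n_cells_entropy_defined: int
    cells: list[CellRecord] = field(default_factory=list)

    def cell_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.cells])

    def summary_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "area_um2": self.area_um2,
            "astrocyte_density_mm2": self.astrocyte_density_mm2,
            "extension_length_density_um_per_um2": self.extension_length_density,
            "branching_density_mm2": self.branching_density_mm2,
            "mean_angle_entropy_bits": self.mean_angle_entropy_bits,
            "n_cells_entropy_defined": self.n_cells_entropy_defined,
        }
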
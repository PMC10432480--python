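"""Seeded synthetic micrographs with exact planted ground truth.

The generator emulates maximum-intensity-projection-like 2D fields of
cortical tissue: astrocyte somata with straight, tree-structured
processes; a connected vessel network of tubes with varying calibre;
punctate connexin-like signal preferentially placed near vessel walls;
neuron-like Gaussian blobs arranged in depth layers below a cortical
surface trace; everything blurred and corrupted with additive Gaussian
noise (clipped to [0, 1]).  Every planted object is recorded in the
scene, so each downstream stage can be scored against exact truth.

Determinism: one integer seed drives a single NumPy PCG64 stream.  The
stream is consumed in a fixed, documented order — somata (radius then
position, rejection-sampled), then per soma: primary count, base angle,
the primaries (angle jitter/flip, length), then per primary the
secondary decision and, if spawned, up to 30 clearance-checked draws of
(attachment, angle, length); then vessels (trunk seeds and walks,
children in spawn order), then puncta (near-vessel placements first),
then neurons (layer by layer).  Rendering noise uses a child stream
seeded by ``(seed, channel_code)``.  Regenerating with the same seed
and parameters is bit-identical.

Geometry conventions: micrometre coordinates ``(y, x)`` with the pixel
``(i, j)`` centred at ``((i + 0.5) ps, (j + 0.5) ps)``; angles in
degrees from the +x axis, so 90° is vertical.  Processes are drawn as
capsules of width ``process_width_px`` (default 2 px); puncta as discs
whose radius is ``sqrt(area / pi)``, i.e. the drawn pixel area is the
disc that best approximates the requested µm² area at the grid
resolution.  A 10 µm border margin contains no object centres, so
recovery tests are free of border-truncation ambiguity.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import BinaryMask, CalibratedImage, LabelMask

__all__ = ["SceneParams", "GroundTruthScene", "generate_scene", "render",
           "Soma", "Branch", "Vessel", "Punctum", "NeuronBlob"]

_CHANNEL_CODES = {"astrocyte": 1, "vessel": 2, "puncta": 3, "neuron": 4}
MARGIN_UM = 10.0


# ---------------------------------------------------------------------------
# Parameters and ground-truth records
# ---------------------------------------------------------------------------


@dataclass
class SceneParams:
    """Knobs of the synthetic scene; defaults are the package's standard
    benchmark conditions (1 mm² field at 1 µm/px, 50 astrocytes/mm² with
    ~40 planted branch junctions, 3 mm of vessel per mm²)."""

    field_size_um: tuple[float, float] = (1000.0, 1000.0)  # (height, width)
    pixel_size_um: float = 1.0
    astrocyte_density_mm2: float = 50.0
    primary_range: tuple[int, int] = (4, 6)  # primaries per soma, inclusive
    secondary_prob: float = 0.16  # chance a primary carries one side branch
    primary_length_um: tuple[float, float] = (15.0, 22.0)
    secondary_length_um: tuple[float, float] = (12.0, 16.0)
    orientation_mode: str = "isotropic"  # or "aligned"
    orientation_axis_deg: float = 90.0
    orientation_jitter_deg: float = 15.0
    soma_radius_um: tuple[float, float] = (4.0, 6.0)
    min_soma_separation_um: float = 70.0
    process_width_px: float = 2.0
    vessel_length_density: float = 0.003  # µm centerline per µm² field
    vessel_radius_um: tuple[float, float] = (1.5, 4.5)
    vessel_step_um: float = 20.0
    vessel_branch_prob: float = 0.1
    n_puncta: int = 150
    puncta_area_um2: tuple[float, float] = (16.0, 30.0)
    puncta_near_vessel_frac: float = 0.8
    puncta_near_dist_um: float = 3.0
    neuron_layers: tuple = ((50.0, 150.0, 300.0), (150.0, 300.0, 600.0),
                           (300.0, 500.0, 400.0))  # (depth_min, depth_max, per mm²)
    neuron_sigma_um: tuple[float, float] = (5.0, 8.0)
    surface_depth_um: float = 10.0
    blur_sigma_um: float = 0.5
    noise_sigma: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        scalars = {
            "pixel_size_um": self.pixel_size_um,
            "astrocyte_density_mm2": self.astrocyte_density_mm2,
            "secondary_prob": self.secondary_prob,
            "min_soma_separation_um": self.min_soma_separation_um,
            "process_width_px": self.process_width_px,
            "vessel_length_density": self.vessel_length_density,
            "vessel_step_um": self.vessel_step_um,
            "vessel_branch_prob": self.vessel_branch_prob,
            "n_puncta": self.n_puncta,
            "puncta_near_vessel_frac": self.puncta_near_vessel_frac,
            "puncta_near_dist_um": self.puncta_near_dist_um,
            "surface_depth_um": self.surface_depth_um,
            "blur_sigma_um": self.blur_sigma_um,
            "noise_sigma": self.noise_sigma,
        }
        for name, v in scalars.items():
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v!r}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for name in ("secondary_prob", "puncta_near_vessel_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.orientation_mode not in ("isotropic", "aligned"):
            raise ValueError("orientation_mode must be 'isotropic' or 'aligned'")
        for name in ("field_size_um", "primary_length_um", "secondary_length_um",
                     "soma_radius_um", "vessel_radius_um", "puncta_area_um2",
                     "neuron_sigma_um"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a finite non-negative (lo, hi) pair")


@dataclass
class Soma:
    center_um: tuple[float, float]  # (y, x)
    radius_um: float


@dataclass
class Branch:
    """One straight process segment; ``parent`` indexes the branch list
    (-1 for a primary, whose first vertex sits on the soma boundary)."""

    cell: int
    parent: int
    vertices_um: list  # [[y, x], [y, x]]

    @property
    def length_um(self) -> float:
        (y0, x0), (y1, x1) = self.vertices_um
        return math.hypot(y1 - y0, x1 - x0)

    @property
    def angle_deg(self) -> float:
        (y0, x0), (y1, x1) = self.vertices_um
        return math.degrees(math.atan2(y1 - y0, x1 - x0)) % 180.0


@dataclass
class Vessel:
    parent: int  # vessel list index, -1 for a trunk
    vertices_um: list  # [[y, x], ...]
    radii_um: list  # per-vertex radius

    @property
    def length_um(self) -> float:
        v = np.asarray(self.vertices_um)
        return float(np.hypot(*(np.diff(v, axis=0).T)).sum())


@dataclass
class Punctum:
    center_um: tuple[float, float]
    area_um2: float


@dataclass
class NeuronBlob:
    center_um: tuple[float, float]
    sigma_um: float
    layer: int


@dataclass
class GroundTruthScene:
    """Planted content of one synthetic field, with exact truth tables."""

    params: SceneParams
    somata: list
    branches: list
    vessels: list
    puncta: list
    neurons: list
    surface_um: list  # polyline [[y, x], ...]
    seed: int

    # -- truth accessors ---------------------------------------------------

    @property
    def field_area_um2(self) -> float:
        h, w = self.params.field_size_um
        return h * w

    def somata_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": np.arange(len(self.somata)),
                "y_um": [s.center_um[0] for s in self.somata],
                "x_um": [s.center_um[1] for s in self.somata],
                "radius_um": [s.radius_um for s in self.somata],
            }
        )

    def segment_angles_deg(self) -> np.ndarray:
        """Orientation of every planted process segment, degrees in [0, 180)."""
        return np.asarray([b.angle_deg for b in self.branches])

    def total_process_length_um(self) -> float:
        return float(sum(b.length_um for b in self.branches))

    def n_primaries(self, cell: int) -> int:
        return sum(1 for b in self.branches if b.cell == cell and b.parent == -1)

    def n_planted_branch_points(self) -> int:
        """Planted branch points under the graph-degree convention:
        one per mid-branch attachment junction, plus one per soma whose
        primary count is >= 3 (the root node then has degree >= 3)."""
        junctions = sum(1 for b in self.branches if b.parent >= 0)
        roots = sum(
            1 for c in range(len(self.somata)) if self.n_primaries(c) >= 3
        )
        return junctions + roots

    def vessel_centerline_length_um(self) -> float:
        return float(sum(v.length_um for v in self.vessels))

    def n_vessel_branch_points(self) -> int:
        return sum(1 for v in self.vessels if v.parent >= 0)

    def puncta_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "y_um": [p.center_um[0] for p in self.puncta],
                "x_um": [p.center_um[1] for p in self.puncta],
                "area_um2": [p.area_um2 for p in self.puncta],
            }
        )

    def neurons_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "y_um": [n.center_um[0] for n in self.neurons],
                "x_um": [n.center_um[1] for n in self.neurons],
                "sigma_um": [n.sigma_um for n in self.neurons],
                "layer": [n.layer for n in self.neurons],
            }
        )

    # -- exact binary rasterizations (no blur, no noise) -------------------

    def _grid_shape(self) -> tuple[int, int]:
        h, w = self.params.field_size_um
        ps = self.params.pixel_size_um
        return (int(round(h / ps)), int(round(w / ps)))

    def soma_label_mask(self) -> LabelMask:
        """Exact label mask of the planted somata (label = cell + 1)."""
        ps = self.params.pixel_size_um
        lab = np.zeros(self._grid_shape(), dtype=np.int32)
        for i, s in enumerate(self.somata):
            _paint_disc_label(lab, s.center_um, s.radius_um, ps, i + 1)
        return LabelMask(lab, ps)

    def vessel_truth_mask(self) -> BinaryMask:
        ps = self.params.pixel_size_um
        canvas = np.zeros(self._grid_shape(), dtype=np.float64)
        _draw_vessels(canvas, self.vessels, ps)
        return BinaryMask(canvas >= 0.5, ps)

    def cell_truth_mask(self, cell: int) -> BinaryMask:
        """Exact mask of one cell (soma disc + process capsules)."""
        ps = self.params.pixel_size_um
        canvas = np.zeros(self._grid_shape(), dtype=np.float64)
        s = self.somata[cell]
        _stamp_capsule(canvas, s.center_um, s.center_um, s.radius_um, ps)
        half_w = 0.5 * self.params.process_width_px * ps
        for b in self.branches:
            if b.cell == cell:
                _stamp_capsule(canvas, b.vertices_um[0], b.vertices_um[1], half_w, ps)
        return BinaryMask(canvas >= 0.5, ps)

    def contacting_cell_ids(self) -> list[int]:
        """Cells whose exact rasterized mask overlaps the exact vessel mask."""
        vm = self.vessel_truth_mask().pixels
        out = []
        for c in range(len(self.somata)):
            if (self.cell_truth_mask(c).pixels & vm).any():
                out.append(c)
        return out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "params": asdict(self.params),
            "seed": self.seed,
            "somata": [asdict(s) for s in self.somata],
            "branches": [asdict(b) for b in self.branches],
            "vessels": [asdict(v) for v in self.vessels],
            "puncta": [asdict(p) for p in self.puncta],
            "neurons": [asdict(n) for n in self.neurons],
            "surface_um": self.surface_um,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthScene":
        p = d["params"]
        for key, val in list(p.items()):
            if isinstance(val, list):
                p[key] = tuple(tuple(x) if isinstance(x, list) else x for x in val)
        return cls(
            params=SceneParams(**p),
            somata=[Soma(tuple(s["center_um"]), s["radius_um"]) for s in d["somata"]],
            branches=[Branch(b["cell"], b["parent"], b["vertices_um"]) for b in d["branches"]],
            vessels=[Vessel(v["parent"], v["vertices_um"], v["radii_um"]) for v in d["vessels"]],
            puncta=[Punctum(tuple(q["center_um"]), q["area_um2"]) for q in d["puncta"]],
            neurons=[NeuronBlob(tuple(n["center_um"]), n["sigma_um"], n["layer"]) for n in d["neurons"]],
            surface_um=d["surface_um"],
            seed=d["seed"],
        )

    def save(self, out_dir) -> None:
        """Write ground truth JSON plus one float32 TIFF per channel."""
        import tifffile

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "scene.json").write_text(json.dumps(self.to_dict(), indent=1))
        for channel in _CHANNEL_CODES:
            img = render(self, channel)
            tifffile.imwrite(
                out / f"{channel}.tif",
                img.pixels.astype(np.float32),
                resolution=(1e4 / img.pixel_size, 1e4 / img.pixel_size),
            )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _unit(angle_deg: float) -> tuple[float, float]:
    a = math.radians(angle_deg)
    return (math.sin(a), math.cos(a))  # (dy, dx); 90° points down rows


def _seg_point_dist(seg_um, point_um) -> float:
    (ay, ax), (by, bx) = seg_um
    py, px_ = point_um
    aby, abx = by - ay, bx - ax
    denom = aby * aby + abx * abx
    t = 0.0 if denom == 0 else max(0.0, min(1.0, ((py - ay) * aby + (px_ - ax) * abx) / denom))
    return math.hypot(py - (ay + t * aby), px_ - (ax + t * abx))


def _clip_segment(start, direction, length, h_um, w_um, lo=1.0):
    """Shorten a segment so its endpoint stays inside [lo, dim - lo]."""
    t = length
    for p0, d, dim in ((start[0], direction[0], h_um), (start[1], direction[1], w_um)):
        if d > 0:
            t = min(t, (dim - lo - p0) / d)
        elif d < 0:
            t = min(t, (lo - p0) / d)
    t = max(t, 0.0)
    return [start[0] + t * direction[0], start[1] + t * direction[1]], t


def generate_scene(params: SceneParams) -> GroundTruthScene:
    """Generate one seeded scene satisfying the planted-content invariants."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    h_um, w_um = params.field_size_um
    area_mm2 = h_um * w_um / 1.0e6

    # 1) somata ------------------------------------------------------------
    n_astro = int(round(params.astrocyte_density_mm2 * area_mm2))
    somata: list[Soma] = []
    for _ in range(n_astro):
        for _attempt in range(20000):
            r = rng.uniform(*params.soma_radius_um)
            y = rng.uniform(MARGIN_UM + r, h_um - MARGIN_UM - r)
            x = rng.uniform(MARGIN_UM + r, w_um - MARGIN_UM - r)
            if all(
                math.hypot(y - s.center_um[0], x - s.center_um[1])
                >= params.min_soma_separation_um
                for s in somata
            ):
                somata.append(Soma((y, x), r))
                break
        else:
            raise RuntimeError(
                "could not place somata at the requested density/separation"
            )

    # 2) processes ----------------------------------------------------------
    # Primaries tile the perimeter (evenly spaced slots with +-0.2-slot
    # jitter), as space-filling astrocyte primaries do; iid angles would
    # plant near-parallel siblings whose rasterized strokes merge into a
    # single medial line, making the planted tree unrecoverable.
    def secondary_angle(parent_angle: float) -> float:
        if params.orientation_mode == "aligned":
            return params.orientation_axis_deg + rng.uniform(
                -params.orientation_jitter_deg, params.orientation_jitter_deg
            )
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return parent_angle + sign * rng.uniform(50.0, 90.0)

    branches: list[Branch] = []
    for ci, s in enumerate(somata):
        k = int(rng.integers(params.primary_range[0], params.primary_range[1] + 1))
        base = rng.uniform(0.0, 360.0)
        cell_first = len(branches)
        prim_angles = []
        for slot in range(k):
            if params.orientation_mode == "aligned":
                flip = 180.0 if rng.random() < 0.5 else 0.0
                ang = params.orientation_axis_deg + flip + rng.uniform(
                    -params.orientation_jitter_deg, params.orientation_jitter_deg
                )
            else:
                ang = base + (slot + rng.uniform(-0.2, 0.2)) * 360.0 / k
            length = rng.uniform(*params.primary_length_um)
            d = _unit(ang)
            start = [s.center_um[0] + s.radius_um * d[0],
                     s.center_um[1] + s.radius_um * d[1]]
            end, _ = _clip_segment(start, d, length, h_um, w_um)
            prim_angles.append(ang)
            branches.append(Branch(ci, -1, [start, end]))
        # Secondaries spawn after all primaries, with a 6 µm clearance to
        # every other branch of the cell: closer siblings would merge into
        # one rasterized stroke and the planted junction would not exist
        # in the image.
        for slot in range(k):
            pi = cell_first + slot
            parent = branches[pi]
            (p0, p1) = parent.vertices_um
            d = _unit(prim_angles[slot])
            t = parent.length_um
            if rng.random() >= params.secondary_prob or t <= 2.0:
                continue
            for _attempt in range(30):
                ta = rng.uniform(0.3, 0.6) * t
                attach = [p0[0] + ta * d[0], p0[1] + ta * d[1]]
                cang = secondary_angle(prim_angles[slot])
                clen = rng.uniform(*params.secondary_length_um)
                cend, ct = _clip_segment(attach, _unit(cang), clen, h_um, w_um)
                mid = [attach[0] + 0.5 * ct * _unit(cang)[0],
                       attach[1] + 0.5 * ct * _unit(cang)[1]]
                clear = True
                for bj in range(cell_first, len(branches)):
                    if bj == pi:
                        continue
                    other = branches[bj]
                    dm = min(
                        _seg_point_dist(other.vertices_um, cend),
                        _seg_point_dist(other.vertices_um, mid),
                    )
                    if dm < 6.0:
                        clear = False
                        break
                if clear:
                    branches.append(Branch(ci, pi, [attach, cend]))
                    break

    # 3) vessels -------------------------------------------------------------
    vessels: list[Vessel] = []
    target = params.vessel_length_density * h_um * w_um
    total = 0.0
    queue: list[tuple] = []  # (parent_idx, start, angle, radius, max_len)
    while total < target:
        if not queue:
            start = [rng.uniform(MARGIN_UM, h_um - MARGIN_UM),
                     rng.uniform(MARGIN_UM, w_um - MARGIN_UM)]
            spec = (-1, start, rng.uniform(0.0, 360.0),
                    rng.uniform(*params.vessel_radius_um), rng.uniform(150.0, 400.0))
        else:
            spec = queue.pop(0)
        parent, start, ang, radius, max_len = spec
        verts = [list(start)]
        walked = 0.0
        idx = len(vessels)
        while walked < max_len:
            ang = ang + rng.normal(0.0, 15.0)
            d = _unit(ang)
            nxt, t = _clip_segment(verts[-1], d, params.vessel_step_um, h_um, w_um)
            if t <= 0.5:  # hit the border
                break
            verts.append(nxt)
            walked += t
            if rng.random() < params.vessel_branch_prob:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                child_r = max(1.0, radius * rng.uniform(0.7, 0.9))
                queue.append(
                    (idx, list(nxt), ang + sign * rng.uniform(30.0, 60.0),
                     child_r, rng.uniform(100.0, 250.0))
                )
            if t < params.vessel_step_um:
                break
        if len(verts) >= 2:
            v = Vessel(parent, verts, [radius] * len(verts))
            vessels.append(v)
            total += v.length_um
        elif parent == -1:
            continue  # degenerate trunk; retry with fresh draws

    # 4) puncta ---------------------------------------------------------------
    puncta: list[Punctum] = []
    n_near = int(round(params.puncta_near_vessel_frac * params.n_puncta))
    for i in range(params.n_puncta):
        area = rng.uniform(*params.puncta_area_um2)
        if i < n_near and vessels:
            for _attempt in range(100):
                v = vessels[int(rng.integers(len(vessels)))]
                si = int(rng.integers(len(v.vertices_um) - 1))
                t = rng.uniform(0.0, 1.0)
                a = np.asarray(v.vertices_um[si])
                b = np.asarray(v.vertices_um[si + 1])
                p = a + t * (b - a)
                seg = b - a
                norm = np.array([-seg[1], seg[0]]) / (np.linalg.norm(seg) or 1.0)
                side = 1.0 if rng.random() < 0.5 else -1.0
                off = v.radii_um[si] + rng.uniform(0.0, params.puncta_near_dist_um)
                c = p + side * off * norm
                if MARGIN_UM <= c[0] <= h_um - MARGIN_UM and MARGIN_UM <= c[1] <= w_um - MARGIN_UM:
                    puncta.append(Punctum((float(c[0]), float(c[1])), area))
                    break
        else:
            c = (rng.uniform(MARGIN_UM, h_um - MARGIN_UM),
                 rng.uniform(MARGIN_UM, w_um - MARGIN_UM))
            puncta.append(Punctum(c, area))

    # 5) neurons --------------------------------------------------------------
    neurons: list[NeuronBlob] = []
    for li, (dmin, dmax, dens) in enumerate(params.neuron_layers):
        y_lo = params.surface_depth_um + dmin
        y_hi = min(params.surface_depth_um + dmax, h_um - MARGIN_UM)
        if y_hi <= y_lo:
            continue
        band_mm2 = (y_hi - y_lo) * (w_um - 2 * MARGIN_UM) / 1.0e6
        n = int(round(dens * band_mm2))
        for _ in range(n):
            c = (rng.uniform(y_lo, y_hi), rng.uniform(MARGIN_UM, w_um - MARGIN_UM))
            neurons.append(NeuronBlob(c, rng.uniform(*params.neuron_sigma_um), li))

    surface = [[params.surface_depth_um, 0.0], [params.surface_depth_um, w_um]]
    return GroundTruthScene(params, somata, branches, vessels, puncta, neurons,
                            surface, params.seed)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _stamp_capsule(canvas, p0_um, p1_um, radius_um, ps) -> None:
    """Max-combine an anti-aliased capsule (segment with round caps).

    Pixel coverage is ``clip(r + 0.5 - d, 0, 1)`` in pixel units, so the
    0.5 level set is exactly ``d <= r``.
    """
    h, w = canvas.shape
    r = radius_um / ps
    a = np.array([p0_um[0] / ps - 0.5, p0_um[1] / ps - 0.5])
    b = np.array([p1_um[0] / ps - 0.5, p1_um[1] / ps - 0.5])
    lo = np.floor(np.minimum(a, b) - r - 1.5).astype(int)
    hi = np.ceil(np.maximum(a, b) + r + 1.5).astype(int)
    y0, x0 = np.maximum(lo, 0)
    y1, x1 = np.minimum(hi + 1, (h, w))
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        dy, dx = yy - a[0], xx - a[1]
    else:
        t = np.clip(((yy - a[0]) * ab[0] + (xx - a[1]) * ab[1]) / denom, 0.0, 1.0)
        dy, dx = yy - (a[0] + t * ab[0]), xx - (a[1] + t * ab[1])
    d = np.sqrt(dy * dy + dx * dx)
    cov = np.clip(r + 0.5 - d, 0.0, 1.0)
    np.maximum(canvas[y0:y1, x0:x1], cov, out=canvas[y0:y1, x0:x1])


def _paint_disc_label(lab, center_um, radius_um, ps, label) -> None:
    h, w = lab.shape
    cy, cx = center_um[0] / ps - 0.5, center_um[1] / ps - 0.5
    r = radius_um / ps
    y0, y1 = max(0, int(cy - r - 1)), min(h, int(cy + r + 2))
    x0, x1 = max(0, int(cx - r - 1)), min(w, int(cx + r + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
    lab[y0:y1, x0:x1][np.hypot(yy - cy, xx - cx) <= r] = label


def _draw_vessels(canvas, vessels, ps) -> None:
    for v in vessels:
        for i in range(len(v.vertices_um) - 1):
            r = 0.5 * (v.radii_um[i] + v.radii_um[i + 1])
            _stamp_capsule(canvas, v.vertices_um[i], v.vertices_um[i + 1], r, ps)


def _stamp_gaussian(canvas, center_um, sigma_um, ps) -> None:
    h, w = canvas.shape
    cy, cx = center_um[0] / ps - 0.5, center_um[1] / ps - 0.5
    s = sigma_um / ps
    ext = 4.0 * s
    y0, y1 = max(0, int(cy - ext)), min(h, int(cy + ext + 2))
    x0, x1 = max(0, int(cx - ext)), min(w, int(cx + ext + 2))
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
    g = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * s * s))
    np.maximum(canvas[y0:y1, x0:x1], g, out=canvas[y0:y1, x0:x1])


def render(scene: GroundTruthScene, channel: str) -> CalibratedImage:
    """Rasterize one channel of a scene, then blur and add noise.

    Planted intensities peak at 1; after the scene's Gaussian blur and
    additive Gaussian noise the result is clipped to [0, 1].  An empty
    channel yields a pure-noise image.
    """
    if channel not in _CHANNEL_CODES:
        raise ValueError(f"unknown channel {channel!r}")
    p = scene.params
    ps = p.pixel_size_um
    canvas = np.zeros(scene._grid_shape(), dtype=np.float64)

    if channel == "astrocyte":
        half_w = 0.5 * p.process_width_px * ps
        for b in scene.branches:
            _stamp_capsule(canvas, b.vertices_um[0], b.vertices_um[1], half_w, ps)
        for s in scene.somata:
            _stamp_capsule(canvas, s.center_um, s.center_um, s.radius_um, ps)
    elif channel == "vessel":
        _draw_vessels(canvas, scene.vessels, ps)
    elif channel == "puncta":
        for q in scene.puncta:
            _stamp_capsule(canvas, q.center_um, q.center_um,
                           math.sqrt(q.area_um2 / math.pi), ps)
    elif channel == "neuron":
        for nb in scene.neurons:
            _stamp_gaussian(canvas, nb.center_um, nb.sigma_um, ps)

    if p.blur_sigma_um > 0:
        from scipy import ndimage as ndi

        canvas = ndi.gaussian_filter(canvas, p.blur_sigma_um / ps, mode="nearest")
    if p.noise_sigma > 0:
        noise_rng = np.random.default_rng([scene.seed, _CHANNEL_CODES[channel]])
        canvas = canvas + p.noise_sigma * noise_rng.standard_normal(canvas.shape)
    return CalibratedImage(np.clip(canvas, 0.0, 1.0), ps, channel)
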
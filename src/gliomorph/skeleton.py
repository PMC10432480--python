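"""Medial lines, skeleton-pixel classification and per-cell graphs.

A binary mask is reduced to a 1-pixel-wide, 8-connected medial line by a
topology-preserving thinning.  Skeleton pixels are classified by their
8-neighbour count: one neighbour marks a termination, three or more a
bifurcation, none an isolated pixel.  Adjacent bifurcation pixels form a
junction cluster that collapses to a single graph node, so branch points
are never double counted.  Each astrocyte becomes a graph whose root
node is the cell body; skeleton pixels inside (or touching) the body
mask are absorbed into the root.  Terminal spur edges shorter than a
pruning threshold (default 4 µm) are removed shortest-first, after which
chains through degree-2 nodes are re-merged.

Two implementation details are deliberate:

* The thinning is made exactly equivariant to 90° rotations by running
  the base thinning in all four axis orientations and selecting a
  canonical result through rotation-invariant integer keys (pixel count,
  integer squared-EDT sums, neighbour-count histogram).  Residual 2x2
  skeleton blocks left by the base pass are eliminated by sequential
  deletion of simple points (8-connectivity foreground, 4-connectivity
  background), which preserves the component count.
* Arc length along a pixel path counts one pixel size per axial step and
  sqrt(2) pixel sizes per diagonal step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import thin as _base_thin

from .core import BinaryMask, LabelMask, STRUCT_4, STRUCT_8

__all__ = [
    "CLASS_LINE",
    "CLASS_TERMINATION",
    "CLASS_BIFURCATION",
    "CLASS_ISOLATED",
    "Skeleton",
    "thin",
    "classify_pixels",
    "path_arc_length",
    "CellGraph",
    "build_graph",
    "prune_graph",
    "skeleton_total_length",
    "split_skeleton_by_bodies",
]

CLASS_LINE = 1
CLASS_TERMINATION = 2
CLASS_BIFURCATION = 3
CLASS_ISOLATED = 4

_SQRT2 = math.sqrt(2.0)
# fixed neighbour scan order: deterministic tracing
_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


@dataclass
class Skeleton:
    """Medial-line pixels of a mask with per-pixel classes."""

    pixels: np.ndarray  # bool grid
    classes: np.ndarray  # uint8 grid: 0 bg, 1 line, 2 term, 3 bif, 4 isolated
    pixel_size: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())

    def count(self, cls: int) -> int:
        return int((self.classes == cls).sum())

    def subset(self, keep: np.ndarray) -> "Skeleton":
        """Skeleton restricted to ``keep``; classes recomputed."""
        px = self.pixels & keep
        return Skeleton(px, _neighbour_classes(px), self.pixel_size)


def _neighbour_counts(px: np.ndarray) -> np.ndarray:
    return ndi.correlate(px.astype(np.uint8), STRUCT_8.astype(np.uint8), mode="constant") - px


def _neighbour_classes(px: np.ndarray) -> np.ndarray:
    n = _neighbour_counts(px)
    cls = np.zeros(px.shape, dtype=np.uint8)
    cls[px] = CLASS_LINE
    cls[px & (n == 1)] = CLASS_TERMINATION
    cls[px & (n >= 3)] = CLASS_BIFURCATION
    cls[px & (n == 0)] = CLASS_ISOLATED
    return cls


def _is_simple(nb: np.ndarray) -> bool:
    """Exact simple-point test on a 3x3 neighbourhood (centre assumed set)."""
    fg = nb.copy()
    fg[1, 1] = False
    if fg.sum() < 2:  # endpoint or isolated: never deleted
        return False
    if ndi.label(fg, structure=STRUCT_8)[1] != 1:
        return False
    lb, _ = ndi.label(~nb, structure=STRUCT_4)
    return len({lb[0, 1], lb[1, 0], lb[1, 2], lb[2, 1]} - {0}) == 1


def _remove_2x2_blocks(s: np.ndarray) -> np.ndarray:
    s = s.copy()
    while True:
        blk = s[:-1, :-1] & s[1:, :-1] & s[:-1, 1:] & s[1:, 1:]
        ys, xs = np.nonzero(blk)
        if len(ys) == 0:
            return s
        sp = np.pad(s, 1)
        changed = False
        for y0, x0 in zip(ys, xs):
            for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
                y, x = y0 + dy, x0 + dx
                if s[y, x] and _is_simple(sp[y : y + 3, x : x + 3].copy()):
                    s[y, x] = False
                    sp[y + 1, x + 1] = False
                    changed = True
        if not changed:
            # remaining blocks are topologically irreducible junctions
            return s


def _thin_once(mask: np.ndarray) -> np.ndarray:
    return _remove_2x2_blocks(_base_thin(mask))


def thin(mask: BinaryMask) -> Skeleton:
    """Topology-preserving thinning to a classified 1-pixel-wide skeleton.

    The skeleton is a subset of the mask, has the same number of
    8-connected components, and is exactly equivariant to 90° rotations
    of the mask.
    """
    m = mask.pixels
    if not m.any():
        empty = np.zeros(m.shape, dtype=bool)
        return Skeleton(empty, np.zeros(m.shape, dtype=np.uint8), mask.pixel_size)
    edt_sq = None
    best_key, best = None, None
    for k in range(4):
        s = np.rot90(_thin_once(np.rot90(m, k)), -k)
        if edt_sq is None:
            edt_sq = np.rint(ndi.distance_transform_edt(m) ** 2).astype(np.int64)
        sq = edt_sq[s]
        nb = _neighbour_counts(s)[s]
        key = (
            int(s.sum()),
            int(sq.sum()),
            int((sq * sq % 1000003).sum()),
            tuple(int(v) for v in np.bincount(nb, minlength=10)),
        )
        if best_key is None or key < best_key:
            best_key, best = key, s
    return Skeleton(best, _neighbour_classes(best), mask.pixel_size)


def classify_pixels(skeleton: Skeleton) -> Skeleton:
    """(Re)assign per-pixel classes from 8-neighbour counts."""
    return Skeleton(
        skeleton.pixels, _neighbour_classes(skeleton.pixels), skeleton.pixel_size
    )


def path_arc_length(path: Sequence[tuple[int, int]], pixel_size: float) -> float:
    """Arc length in µm of an 8-connected pixel path."""
    total = 0.0
    for (y0, x0), (y1, x1) in zip(path[:-1], path[1:]):
        dy, dx = abs(y1 - y0), abs(x1 - x0)
        if max(dy, dx) != 1:
            raise ValueError(
                f"consecutive path pixels {(y0, x0)} and {(y1, x1)} are not 8-adjacent"
            )
        total += _SQRT2 if dy + dx == 2 else 1.0
    return total * pixel_size


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


@dataclass
class CellGraph:
    """Per-cell (or per-vessel-component) medial-line graph.

    Nodes carry ``kind`` (root / bifurcation / termination / anchor),
    ``pos_um`` and their member ``pixels``.  Edges carry ``length_um``
    and the traced pixel ``path``.  ``rootless`` graphs come from
    skeleton components with no associated body; they enter sample-level
    totals but are excluded from per-cell statistics.
    """

    graph: nx.MultiGraph
    pixel_size: float
    cell_id: Optional[int] = None
    rootless: bool = False

    @property
    def n_branch_points(self) -> int:
        """Nodes with degree >= 3 (a root with >= 3 edges counts)."""
        return sum(1 for _, d in self.graph.degree() if d >= 3)

    @property
    def n_terminations(self) -> int:
        return sum(1 for _, k in self.graph.nodes(data="kind") if k == "termination")

    @property
    def total_length_um(self) -> float:
        return float(
            sum(d["length_um"] for _, _, d in self.graph.edges(data=True))
        )

    @property
    def root(self) -> Optional[int]:
        for n, k in self.graph.nodes(data="kind"):
            if k == "root":
                return n
        return None

    def to_dict(self) -> dict:
        """JSON-serializable representation (positions in µm)."""
        nodes = [
            {
                "id": int(n),
                "kind": d["kind"],
                "y_um": float(d["pos_um"][0]),
                "x_um": float(d["pos_um"][1]),
            }
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        edges = [
            {
                "u": int(u),
                "v": int(v),
                "length_um": float(d["length_um"]),
                "path": [[int(y), int(x)] for y, x in d["path"]],
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return {
            "cell_id": self.cell_id,
            "rootless": self.rootless,
            "pixel_size_um": self.pixel_size,
            "nodes": nodes,
            "edges": edges,
        }


def _px_center_um(pixel: tuple[int, int], pixel_size: float) -> tuple[float, float]:
    return ((pixel[0] + 0.5) * pixel_size, (pixel[1] + 0.5) * pixel_size)


def build_graph(
    skeleton: Skeleton,
    body: Optional[BinaryMask] = None,
    prune_below_um: float = 4.0,
    cell_id: Optional[int] = None,
) -> CellGraph:
    """Build (and prune) the graph of one skeleton.

    ``body``, when given, defines the root: skeleton pixels on or
    8-adjacent to the body mask collapse into a single root node placed
    at the member pixel nearest the body centroid.  A skeleton that does
    not touch the body (or ``body is None``) yields a rootless graph.
    Terminal edges with arc length strictly below ``prune_below_um`` are
    removed iteratively (shortest first), then chains through degree-2
    nodes are re-merged.
    """
    px = skeleton.pixels
    ps = skeleton.pixel_size
    h, w = px.shape
    ncnt = _neighbour_counts(px)

    root_region = np.zeros_like(px)
    root_pos = None
    if body is not None and body.pixels.any():
        zone = ndi.binary_dilation(body.pixels, structure=STRUCT_8)
        root_region = px & zone
        if root_region.any():
            ys, xs = np.nonzero(body.pixels)
            cy, cx = float(ys.mean()), float(xs.mean())
            ry, rx = np.nonzero(root_region)
            i = int(np.argmin((ry - cy) ** 2 + (rx - cx) ** 2))
            root_pos = _px_center_um((int(ry[i]), int(rx[i])), ps)

    junction = px & (ncnt >= 3) & ~root_region
    term = px & (ncnt == 1) & ~root_region

    node_id = np.full((h, w), -1, dtype=np.int64)
    g = nx.MultiGraph()
    next_id = 0
    if root_region.any():
        pix = [tuple(p) for p in np.argwhere(root_region)]
        g.add_node(next_id, kind="root", pos_um=root_pos, pixels=pix)
        for p in pix:
            node_id[p] = next_id
        next_id += 1
    jl, nj = ndi.label(junction, structure=STRUCT_8)
    for lab in range(1, nj + 1):
        pix = [tuple(p) for p in np.argwhere(jl == lab)]
        cen = np.mean(pix, axis=0)
        pos = _px_center_um((int(round(cen[0])), int(round(cen[1]))), ps)
        g.add_node(next_id, kind="bifurcation", pos_um=pos, pixels=pix)
        for p in pix:
            node_id[p] = next_id
        next_id += 1
    for p in map(tuple, np.argwhere(term)):
        g.add_node(next_id, kind="termination", pos_um=_px_center_um(p, ps), pixels=[p])
        node_id[p] = next_id
        next_id += 1

    visited = np.zeros_like(px)  # consumed line pixels
    direct_pairs: set[tuple[int, int]] = set()

    def neighbours(p):
        y, x = p
        for dy, dx in _OFFSETS:
            ny, nx_ = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx_ < w and px[ny, nx_]:
                yield (ny, nx_)

    def walk(start_pixel, first):
        """Trace from a node pixel through line pixels to the next node."""
        path = [start_pixel, first]
        prev, cur = start_pixel, first
        while True:
            visited[cur] = True
            nxt = None
            for q in neighbours(cur):
                if q == prev:
                    continue
                if node_id[q] >= 0:
                    path.append(q)
                    return path, int(node_id[q])
                if not visited[q]:
                    nxt = q
                    break
            if nxt is None:
                # dead end inside line pixels (degenerate); treat last as end
                return path, None
            path.append(nxt)
            prev, cur = cur, nxt

    for n in sorted(g.nodes):
        for sp in sorted(g.nodes[n]["pixels"]):
            for q in sorted(neighbours(sp)):
                other = int(node_id[q])
                if other >= 0:
                    if other != n:
                        pair = (min(n, other), max(n, other))
                        if pair not in direct_pairs:
                            direct_pairs.add(pair)
                            g.add_edge(
                                n,
                                other,
                                length_um=path_arc_length([sp, q], ps),
                                path=[sp, q],
                            )
                    continue
                if visited[q]:
                    continue
                path, end = walk(sp, q)
                if end is None:
                    # chain ended without reaching a node (only possible in
                    # degenerate subsets); close it as a termination
                    p_end = path[-1]
                    g.add_node(
                        next_id,
                        kind="termination",
                        pos_um=_px_center_um(p_end, ps),
                        pixels=[p_end],
                    )
                    node_id[p_end] = next_id
                    end = next_id
                    next_id += 1
                g.add_edge(n, end, length_um=path_arc_length(path, ps), path=path)

    # pure cycles: components made of line pixels only
    remaining = px & ~visited & (node_id < 0) & (ncnt > 0)
    while remaining.any():
        ys, xs = np.nonzero(remaining)
        anchor = (int(ys[0]), int(xs[0]))  # lexicographically smallest
        g.add_node(
            next_id, kind="anchor", pos_um=_px_center_um(anchor, ps), pixels=[anchor]
        )
        node_id[anchor] = next_id
        first = sorted(neighbours(anchor))[0]
        path, end = walk(anchor, first)
        g.add_edge(next_id, end if end is not None else next_id,
                   length_um=path_arc_length(path, ps), path=path)
        next_id += 1
        remaining = px & ~visited & (node_id < 0) & (ncnt > 0)

    cg = CellGraph(g, ps, cell_id=cell_id, rootless=root_pos is None)
    if prune_below_um > 0:
        prune_graph(cg, prune_below_um)
    _refresh_kinds(cg.graph)
    return cg


def _refresh_kinds(g: nx.MultiGraph) -> None:
    for n in g.nodes:
        if g.nodes[n]["kind"] == "root":
            continue
        d = g.degree(n)
        if d >= 3:
            g.nodes[n]["kind"] = "bifurcation"
        elif d == 1:
            g.nodes[n]["kind"] = "termination"
        elif d == 2:
            if g.nodes[n]["kind"] != "anchor":
                g.nodes[n]["kind"] = "line"


def _merge_degree2(g: nx.MultiGraph) -> None:
    """Collapse non-root degree-2 nodes by concatenating their two edges."""
    changed = True
    while changed:
        changed = False
        for n in sorted(g.nodes):
            if g.nodes[n]["kind"] == "root" or g.degree(n) != 2:
                continue
            inc = list(g.edges(n, keys=True, data=True))
            if len(inc) != 2:  # self-loop counts twice: keep as anchored cycle
                continue
            (u1, v1, k1, d1), (u2, v2, k2, d2) = inc
            a = v1 if u1 == n else u1
            b = v2 if u2 == n else u2
            p1 = d1["path"] if d1["path"][-1] in g.nodes[n]["pixels"] else d1["path"][::-1]
            p2 = d2["path"] if d2["path"][0] in g.nodes[n]["pixels"] else d2["path"][::-1]
            new_path = p1 + p2[1:]
            g.remove_edge(u1, v1, key=k1)
            g.remove_edge(u2, v2, key=k2)
            g.remove_node(n)
            g.add_edge(a, b, length_um=d1["length_um"] + d2["length_um"], path=new_path)
            changed = True
            break


def prune_graph(cg: CellGraph, prune_below_um: float = 4.0) -> CellGraph:
    """Iteratively remove short terminal (spur) edges, shortest first.

    Only edges incident to a non-root degree-1 node are candidates, so
    the graph never disconnects.  After each removal, chains through
    degree-2 nodes are re-merged and node kinds refreshed.  Pruning a
    pruned graph changes nothing (idempotent).
    """
    g = cg.graph
    while True:
        candidates = []
        for u, v, k, d in g.edges(keys=True, data=True):
            if d["length_um"] >= prune_below_um:
                continue
            for end in (u, v):
                if g.degree(end) == 1 and g.nodes[end]["kind"] != "root":
                    candidates.append(
                        (d["length_um"], g.nodes[end]["pos_um"], u, v, k, end)
                    )
                    break
        if not candidates:
            break
        candidates.sort(key=lambda c: (c[0], c[1]))
        _, _, u, v, k, end = candidates[0]
        g.remove_edge(u, v, key=k)
        for n in (u, v):
            if n in g and g.degree(n) == 0 and g.nodes[n]["kind"] != "root":
                g.remove_node(n)
        _merge_degree2(g)
        _refresh_kinds(g)
    _refresh_kinds(g)
    return cg


def skeleton_total_length(skeleton: Skeleton) -> float:
    """Total arc length (µm) of all medial lines of a skeleton.

    Computed by tracing the unpruned path decomposition; isolated pixels
    contribute zero length.
    """
    cg = build_graph(skeleton, body=None, prune_below_um=0.0)
    return cg.total_length_um


def split_skeleton_by_bodies(
    skeleton: Skeleton, bodies: LabelMask
) -> list[tuple[Optional[int], np.ndarray]]:
    """Assign each skeleton component to a body.

    Returns ``(body_label_or_None, pixel_mask)`` entries.  A component
    intersecting the (1-pixel-dilated) mask of exactly one body belongs
    to it; components touching several bodies are split by the
    nearest-body label of each pixel; components touching none are
    returned with label ``None`` (rootless).
    """
    px = skeleton.pixels
    comp, nc = ndi.label(px, structure=STRUCT_8)
    if nc == 0:
        return []
    body_zone = ndi.grey_dilation(bodies.pixels, footprint=STRUCT_8)
    out: list[tuple[Optional[int], np.ndarray]] = []
    nearest = None
    for c in range(1, nc + 1):
        cm = comp == c
        hits = np.unique(body_zone[cm])
        hits = hits[hits > 0]
        if hits.size == 0:
            out.append((None, cm))
        elif hits.size == 1:
            out.append((int(hits[0]), cm))
        else:
            if nearest is None:
                ind = ndi.distance_transform_edt(
                    bodies.pixels == 0, return_indices=True
                )[1]
                nearest = bodies.pixels[ind[0], ind[1]]
            for lab in hits:
                out.append((int(lab), cm & (nearest == lab)))
    return out
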
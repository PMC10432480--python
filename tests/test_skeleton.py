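"""Thinning, pixel classification, arc lengths and per-cell graphs."""

import math

import numpy as np
import pytest
from scipy import ndimage as ndi

import gliomorph as gm
from gliomorph import skeleton as sk

from conftest import mask, random_blob_mask

S8 = np.ones((3, 3), bool)


def ncomp(m):
    return ndi.label(m, structure=S8)[1]


def has_2x2_block(s):
    return bool(np.any(s[:-1, :-1] & s[1:, :-1] & s[:-1, 1:] & s[1:, 1:]))


def bar_mask(h=3, w=15, pad=3):
    arr = np.zeros((h + 2 * pad, w + 2 * pad), bool)
    arr[pad : pad + h, pad : pad + w] = True
    return arr


def plus_mask(arm=8, width=3, pad=3):
    n = 2 * arm + width + 2 * pad
    arr = np.zeros((n, n), bool)
    c = pad + arm
    arr[c : c + width, pad : n - pad] = True
    arr[pad : n - pad, c : c + width] = True
    return arr


class TestThin:
    def test_solid_bar_thins_to_simple_path(self):
        skel = sk.thin(mask(bar_mask()))
        assert skel.count(sk.CLASS_TERMINATION) == 2
        assert skel.count(sk.CLASS_BIFURCATION) == 0
        assert ncomp(skel.pixels) == 1
        assert not has_2x2_block(skel.pixels)

    def test_single_pixel_is_isolated(self):
        arr = np.zeros((7, 7), bool)
        arr[3, 3] = True
        skel = sk.thin(mask(arr))
        assert skel.pixels[3, 3] and skel.n_pixels == 1
        assert skel.count(sk.CLASS_ISOLATED) == 1

    def test_plus_sign_has_four_terminations_and_one_junction_cluster(self):
        skel = sk.thin(mask(plus_mask()))
        assert skel.count(sk.CLASS_TERMINATION) == 4
        bif = skel.classes == sk.CLASS_BIFURCATION
        assert bif.sum() >= 1
        assert ncomp(bif) == 1  # one junction cluster

    def test_empty_mask_gives_empty_skeleton(self):
        skel = sk.thin(mask(np.zeros((5, 5))))
        assert skel.n_pixels == 0

    def test_skeleton_is_subset_of_mask(self, rng):
        for _ in range(10):
            m = random_blob_mask(rng)
            skel = sk.thin(mask(m))
            assert not (skel.pixels & ~m).any()

    def test_rot90_equivariance_on_random_blobs(self, rng):
        for _ in range(15):
            m = random_blob_mask(rng)
            s = sk.thin(mask(m)).pixels
            s_rot = sk.thin(mask(np.rot90(m).copy())).pixels
            np.testing.assert_array_equal(s_rot, np.rot90(s))


class TestClassifyPixels:
    def test_straight_line_classes(self):
        arr = np.zeros((5, 14), bool)
        arr[2, 2:12] = True  # 10-pixel line
        skel = sk.classify_pixels(sk.Skeleton(arr, None, 1.0))
        assert skel.count(sk.CLASS_TERMINATION) == 2
        assert skel.count(sk.CLASS_LINE) == 8

    def test_y_shape_has_three_terminations_one_junction(self):
        arr = np.zeros((16, 16), bool)
        arr[2:9, 8] = True          # stem down to (8, 8)
        for i in range(1, 6):       # two diagonal arms
            arr[8 + i, 8 - i] = True
            arr[8 + i, 8 + i] = True
        skel = sk.classify_pixels(sk.Skeleton(arr, None, 1.0))
        assert skel.count(sk.CLASS_TERMINATION) == 3
        assert ncomp(skel.classes == sk.CLASS_BIFURCATION) == 1

    def test_isolated_pixel_class(self):
        arr = np.zeros((4, 4), bool)
        arr[1, 2] = True
        skel = sk.classify_pixels(sk.Skeleton(arr, None, 1.0))
        assert skel.classes[1, 2] == sk.CLASS_ISOLATED


class TestPathArcLength:
    def test_axial_and_diagonal_steps(self):
        horiz = [(3, x) for x in range(11)]
        assert sk.path_arc_length(horiz, 0.5) == pytest.approx(5.0)
        diag = [(i, i) for i in range(11)]
        assert sk.path_arc_length(diag, 0.5) == pytest.approx(5 * math.sqrt(2))

    def test_concatenation_additivity(self):
        a = [(0, 0), (0, 1), (1, 2)]
        b = [(1, 2), (2, 2), (3, 3), (3, 4)]
        whole = a + b[1:]
        assert sk.path_arc_length(whole, 1.0) == pytest.approx(
            sk.path_arc_length(a, 1.0) + sk.path_arc_length(b, 1.0)
        )

    def test_non_adjacent_pixels_rejected(self):
        with pytest.raises(ValueError):
            sk.path_arc_length([(0, 0), (0, 2)], 1.0)


def _y_skeleton(arm=8):
    """Y-shaped skeleton with stem start at (2, 12)."""
    arr = np.zeros((26, 26), bool)
    arr[2:13, 12] = True
    for i in range(1, arm + 1):
        arr[12 + i, 12 - i] = True
        arr[12 + i, 12 + i] = True
    return arr


class TestBuildGraph:
    def test_y_with_body_at_stem(self):
        arr = _y_skeleton()
        body = np.zeros_like(arr)
        body[1:5, 10:15] = True  # covers the stem end
        skel = sk.classify_pixels(sk.Skeleton(arr, None, 1.0))
        g = sk.build_graph(skel, gm.BinaryMask(body, 1.0), prune_below_um=4.0)
        kinds = sorted(d["kind"] for _, d in g.graph.nodes(data=True))
        assert kinds == ["bifurcation", "root", "termination", "termination"]
        assert g.graph.number_of_edges() == 3
        assert not g.rootless

    def test_short_stub_is_pruned_to_single_path(self):
        # T-shape whose crossbar stub is 3 um (< 4 um prune threshold)
        arr = np.zeros((20, 30), bool)
        arr[10, 2:25] = True
        arr[11:14, 13] = True  # 3-pixel stub
        body = np.zeros_like(arr)
        body[8:13, 0:4] = True
        skel = sk.classify_pixels(sk.Skeleton(arr, None, 1.0))
        g = sk.build_graph(skel, gm.BinaryMask(body, 1.0), prune_below_um=4.0)
        kinds = sorted(d["kind"] for _, d in g.graph.nodes(data=True))
        assert kinds == ["root", "termination"]
        assert g.graph.number_of_edges() == 1
        assert g.n_branch_points == 0

    def test_path_without_body_is_rootless(self):
        arr = np.zeros((5, 20), bool)
        arr[2, 2:18] = True
        skel = sk.classify_pixels(sk.Skeleton(arr, None, 1.0))
        g = sk.build_graph(skel, None, prune_below_um=4.0)
        assert g.rootless
        assert g.n_terminations == 2
        assert g.total_length_um == pytest.approx(15.0)

    def test_pruning_is_idempotent(self, rng):
        for _ in range(10):
            m = random_blob_mask(rng, n=40, sigma=2.5)
            skel = sk.thin(mask(m))
            for comp_lab in range(1, ncomp(skel.pixels) + 1):
                comp = ndi.label(skel.pixels, structure=S8)[0] == comp_lab
                g = sk.build_graph(skel.subset(comp), None, prune_below_um=4.0)
                before = (g.graph.number_of_nodes(), g.graph.number_of_edges(),
                          round(g.total_length_um, 9))
                sk.prune_graph(g, 4.0)
                after = (g.graph.number_of_nodes(), g.graph.number_of_edges(),
                         round(g.total_length_um, 9))
                assert before == after

    def test_no_terminal_edge_below_threshold_after_pruning(self, rng):
        for _ in range(10):
            m = random_blob_mask(rng, n=40, sigma=2.0)
            skel = sk.thin(mask(m))
            lab, n = ndi.label(skel.pixels, structure=S8)
            for c in range(1, n + 1):
                g = sk.build_graph(skel.subset(lab == c), None, prune_below_um=4.0)
                for u, v, d in g.graph.edges(data=True):
                    if d["length_um"] < 4.0:
                        deg_u, deg_v = g.graph.degree(u), g.graph.degree(v)
                        assert min(deg_u, deg_v) > 1  # interior edges may stay

    def test_graph_length_bounded_by_skeleton_length(self, rng):
        for _ in range(8):
            m = random_blob_mask(rng, n=40, sigma=2.0)
            skel = sk.thin(mask(m))
            total = sk.skeleton_total_length(skel)
            lab, n = ndi.label(skel.pixels, structure=S8)
            pruned = sum(
                sk.build_graph(skel.subset(lab == c), None, 4.0).total_length_um
                for c in range(1, n + 1)
            )
            assert pruned <= total + 1e-9

    def test_arc_lengths_invariant_under_rotation(self, rng):
        for _ in range(8):
            m = random_blob_mask(rng, n=36, sigma=2.0)
            a = sk.skeleton_total_length(sk.thin(mask(m)))
            b = sk.skeleton_total_length(sk.thin(mask(np.rot90(m).copy())))
            assert a == pytest.approx(b, rel=1e-12)


class TestSplitByBodies:
    def test_component_touching_two_bodies_is_split_by_nearest(self):
        arr = np.zeros((9, 40), bool)
        arr[4, 2:38] = True  # one line spanning both bodies
        lab = np.zeros((9, 40), np.int32)
        lab[3:6, 0:4] = 1
        lab[3:6, 36:40] = 2
        bodies = gm.LabelMask(lab, 1.0)
        skel = sk.classify_pixels(sk.Skeleton(arr, None, 1.0))
        parts = dict()
        for body_label, pm in sk.split_skeleton_by_bodies(skel, bodies):
            parts[body_label] = pm
        assert set(parts) == {1, 2}
        ys, xs1 = np.nonzero(parts[1])
        ys, xs2 = np.nonzero(parts[2])
        assert xs1.max() < xs2.min()  # left half vs right half
        assert (parts[1].sum() + parts[2].sum()) == arr.sum()

    def test_component_touching_no_body_is_rootless(self):
        arr = np.zeros((9, 20), bool)
        arr[4, 2:18] = True
        bodies = gm.LabelMask(np.zeros((9, 20), np.int32), 1.0)
        parts = sk.split_skeleton_by_bodies(
            sk.classify_pixels(sk.Skeleton(arr, None, 1.0)), bodies
        )
        assert len(parts) == 1 and parts[0][0] is None
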
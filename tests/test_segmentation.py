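"""Segmentation operator contracts: windowed means, thresholds, filters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gliomorph as gm
from gliomorph import segmentation as seg

from conftest import brute_circular_mean, image, mask


class TestGaussianSmooth:
    def test_zero_sigma_is_identity(self, rng):
        img = image(rng.random((20, 20)))
        out = seg.gaussian_smooth(img, 0.0)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_constant_image_stays_constant(self):
        img = image(np.full((16, 16), 0.37))
        out = seg.gaussian_smooth(img, 3.0)
        np.testing.assert_allclose(out.pixels, 0.37, rtol=0, atol=1e-12)

    def test_impulse_center_matches_discrete_gaussian(self):
        # centre of the impulse response = squared 1D normalized weight
        arr = np.zeros((41, 41))
        arr[20, 20] = 1.0
        sigma = 2.0
        out = seg.gaussian_smooth(image(arr), sigma)
        k = np.arange(-int(4 * sigma + 0.5), int(4 * sigma + 0.5) + 1)
        w = np.exp(-(k**2) / (2 * sigma**2))
        w0 = w[len(k) // 2] / w.sum()
        assert abs(out.pixels[20, 20] - w0 * w0) < 1e-6

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            seg.gaussian_smooth(image(np.zeros((4, 4))), -1.0)


class TestLocalCircularMean:
    def test_constant_image_unchanged(self):
        img = image(np.full((15, 15), 0.5))
        out = seg.local_circular_mean(img, 4.0)
        np.testing.assert_allclose(out.pixels, 0.5, atol=1e-12)

    def test_five_pixel_disc_center_value(self):
        # radius 1 px covers the 5-pixel plus-shaped disc
        arr = np.zeros((11, 11))
        arr[5, 5] = 1.0
        out = seg.local_circular_mean(image(arr), 1.0)
        assert out.pixels[5, 5] == pytest.approx(1 / 5, abs=1e-12)

    @pytest.mark.parametrize("radius", [1, 2, 3, 4, 5])
    def test_matches_brute_force_on_random_grids(self, rng, radius):
        for _ in range(4):
            arr = rng.random((16, 16))
            out = seg.local_circular_mean(image(arr), float(radius))
            np.testing.assert_allclose(
                out.pixels, brute_circular_mean(arr, radius), rtol=0, atol=1e-10
            )

    def test_subpixel_radius_rejected(self):
        with pytest.raises(ValueError):
            seg.local_circular_mean(image(np.zeros((8, 8)), pixel_size=2.0), 1.0)


class TestAdaptiveLocalThreshold:
    def test_constant_image_yields_empty_mask(self):
        out = seg.adaptive_local_threshold(image(np.full((30, 30), 0.4)), 5.0)
        assert not out.pixels.any()

    def test_bright_square_on_dark_background(self):
        arr = np.zeros((21, 21))
        arr[9:12, 9:12] = 1.0
        out = seg.adaptive_local_threshold(image(arr), 20.0)
        assert out.pixels[9:12, 9:12].all()
        rest = out.pixels.copy()
        rest[9:12, 9:12] = False
        assert not rest.any()

    def test_inverted_foreground_disjoint_from_original(self, rng):
        arr = rng.random((24, 24))
        a = seg.adaptive_local_threshold(image(arr), 4.0)
        b = seg.adaptive_local_threshold(image(1.0 - arr), 4.0)
        assert not (a.pixels & b.pixels).any()

    def test_invariant_under_positive_affine_rescale(self, rng):
        arr = rng.random((24, 24))
        a = seg.adaptive_local_threshold(image(arr), 4.0)
        b = seg.adaptive_local_threshold(image(4.0 * arr + 0.25), 4.0)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestRemoveSmallComponents:
    def test_threshold_boundary_semantics(self):
        # 10 um^2 removed, exactly 25 um^2 kept, 30 um^2 kept
        arr = np.zeros((40, 40), bool)
        arr[2:4, 2:7] = True          # 10 px = 10 um^2
        arr[10:15, 10:15] = True      # 25 px = 25 um^2 exactly
        arr[25:30, 25:31] = True      # 30 px
        out = seg.remove_small_components(mask(arr), 25.0)
        assert not out.pixels[2:4, 2:7].any()
        assert out.pixels[10:15, 10:15].all()
        assert out.pixels[25:30, 25:31].all()

    def test_empty_mask_passes_through(self):
        out = seg.remove_small_components(mask(np.zeros((8, 8))), 25.0)
        assert not out.pixels.any()

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), min_area=st.floats(0, 30))
    def test_never_adds_pixels_and_keeps_survivors_intact(self, seed, min_area):
        rng = np.random.default_rng(seed)
        arr = rng.random((24, 24)) < 0.3
        out = seg.remove_small_components(mask(arr), min_area)
        assert not (out.pixels & ~arr).any()
        # every surviving component is bitwise identical to its source
        from scipy import ndimage as ndi

        lab, n = ndi.label(arr, structure=np.ones((3, 3)))
        for c in range(1, n + 1):
            comp = lab == c
            inter = (out.pixels & comp).sum()
            assert inter in (0, comp.sum())

    def test_connectivity_choice_matters_for_diagonal_links(self):
        arr = np.zeros((10, 10), bool)
        arr[2:5, 2:5] = True
        arr[5, 5] = True  # diagonally attached pixel
        out8 = seg.remove_small_components(mask(arr), 10.0, connectivity=8)
        out4 = seg.remove_small_components(mask(arr), 10.0, connectivity=4)
        assert out8.pixels[5, 5]          # part of a 10 px component
        assert not out4.pixels[5, 5]      # isolated 1 px component under 4-conn


class TestSegmentProcesses:
    def test_blank_image_returns_body_mask(self):
        img = image(np.zeros((60, 60)))
        lab = np.zeros((60, 60), np.int32)
        lab[20:25, 20:25] = 1
        bodies = gm.LabelMask(lab, 1.0)
        out = seg.segment_processes(img, bodies)
        np.testing.assert_array_equal(out.pixels, bodies.pixels > 0)

    def test_small_speck_far_from_bodies_is_filtered(self):
        arr = np.zeros((80, 80))
        arr[10:12, 10:13] = 1.0  # 6 um^2 speck, below the 25 um^2 filter
        bodies = gm.LabelMask(np.zeros((80, 80), np.int32), 1.0)
        out = seg.segment_processes(image(arr), bodies, smooth_sigma_um=0.0)
        assert not out.pixels.any()

    def test_planted_processes_covered_after_one_pixel_dilation(self):
        from scipy import ndimage as ndi

        p = gm.SceneParams(field_size_um=(300, 300), seed=5, noise_sigma=0.0)
        scene = gm.generate_scene(p)
        img = gm.render(scene, "astrocyte")
        bodies = scene.soma_label_mask()
        out = seg.segment_processes(img, bodies)
        dil = ndi.binary_dilation(out.pixels, np.ones((3, 3), bool))
        for b in scene.branches:
            (y0, x0), (y1, x1) = b.vertices_um
            n = max(2, int(b.length_um * 2))
            ys = np.clip(np.round(np.linspace(y0, y1, n) - 0.5).astype(int), 0, 299)
            xs = np.clip(np.round(np.linspace(x0, x1, n) - 0.5).astype(int), 0, 299)
            assert dil[ys, xs].all()


class TestDetectBodies:
    def test_blank_image_yields_empty_label_mask(self):
        out = seg.detect_bodies(image(np.zeros((50, 50))))
        assert out.n_objects == 0

    def test_two_well_separated_somata_are_never_merged(self):
        arr = np.zeros((120, 120))
        yy, xx = np.mgrid[0:120, 0:120]
        for cy, cx in ((40, 40), (40, 80)):  # separation 40 > 2x radius
            arr = np.maximum(arr, (np.hypot(yy - cy, xx - cx) <= 5).astype(float))
        out = seg.detect_bodies(image(arr))
        assert out.n_objects == 2
        xs = sorted(out.table["centroid_x_um"])
        assert abs(xs[0] - 40.5) < 0.8 and abs(xs[1] - 80.5) < 0.8

    def test_external_detector_is_used_verbatim(self):
        marker = gm.LabelMask(np.ones((10, 10), np.int32), 1.0)
        out = seg.detect_bodies(
            image(np.zeros((10, 10))), detector=lambda img, cfg: marker
        )
        assert out is marker


class TestSegmentVessels:
    def test_blank_image_yields_empty_mask(self):
        assert not seg.segment_vessels(image(np.zeros((40, 40)))).pixels.any()

    def test_invariant_under_constant_offset(self, rng):
        p = gm.SceneParams(field_size_um=(250, 250), seed=2, noise_sigma=0.0,
                           astrocyte_density_mm2=0, n_puncta=0, neuron_layers=())
        scene = gm.generate_scene(p)
        img = gm.render(scene, "vessel")
        a = seg.segment_vessels(img)
        shifted = gm.CalibratedImage(img.pixels * 0.5 + 0.25, 1.0)
        b = seg.segment_vessels(shifted)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestSegmentPuncta:
    def test_planted_puncta_each_survive_as_one_component(self):
        from scipy import ndimage as ndi

        p = gm.SceneParams(field_size_um=(300, 300), seed=7, noise_sigma=0.0,
                           astrocyte_density_mm2=0, neuron_layers=(),
                           n_puncta=12, puncta_area_um2=(20.0, 20.0),
                           puncta_near_vessel_frac=0.0, vessel_length_density=0.0)
        scene = gm.generate_scene(p)
        out = seg.segment_puncta(gm.render(scene, "puncta"))
        lab, n = ndi.label(out.pixels, structure=np.ones((3, 3)))
        # puncta may occasionally be planted overlapping; count distinct sites
        centers = np.round(scene.puncta_table()[["y_um", "x_um"]].to_numpy() - 0.5)
        hit = {int(lab[int(y), int(x)]) for y, x in centers}
        assert 0 not in hit and len(hit) == n

    def test_puncta_below_fifteen_um2_vanish(self):
        p = gm.SceneParams(field_size_um=(200, 200), seed=7, noise_sigma=0.0,
                           blur_sigma_um=0.0,
                           astrocyte_density_mm2=0, neuron_layers=(),
                           n_puncta=8, puncta_area_um2=(6.0, 8.0),
                           puncta_near_vessel_frac=0.0, vessel_length_density=0.0)
        scene = gm.generate_scene(p)
        out = seg.segment_puncta(gm.render(scene, "puncta"), smooth_sigma_um=0.0)
        assert not out.pixels.any()

    def test_constant_image_yields_empty_mask(self):
        assert not seg.segment_puncta(image(np.full((60, 60), 0.3))).pixels.any()
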
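"""Scene generator: determinism, planted-content invariants, rendering."""

import json
import math

import numpy as np
import pytest

import gliomorph as gm
from gliomorph.synthetic import (
    MARGIN_UM,
    GroundTruthScene,
    SceneParams,
    Soma,
    Vessel,
    generate_scene,
    render,
)


def small_params(**kw):
    base = dict(field_size_um=(300.0, 300.0), seed=11, noise_sigma=0.0)
    base.update(kw)
    return SceneParams(**base)


class TestGenerateScene:
    def test_same_seed_reproduces_scene_and_render_bit_identically(self):
        p1, p2 = small_params(), small_params()
        s1, s2 = generate_scene(p1), generate_scene(p2)
        assert s1.to_dict() == s2.to_dict()
        for channel in ("astrocyte", "vessel", "puncta", "neuron"):
            np.testing.assert_array_equal(
                render(s1, channel).pixels, render(s2, channel).pixels
            )

    def test_rendered_noise_is_seeded(self):
        p = small_params(noise_sigma=0.05)
        a = render(generate_scene(p), "astrocyte")
        b = render(generate_scene(p), "astrocyte")
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_planted_soma_count_is_exact(self):
        p = SceneParams(seed=0, noise_sigma=0.0)  # 1 mm^2 at 50 cells/mm^2
        assert len(generate_scene(p).somata) == 50

    def test_rejects_invalid_parameters(self):
        for bad in (
            dict(astrocyte_density_mm2=-1),
            dict(noise_sigma=float("nan")),
            dict(secondary_prob=1.5),
            dict(orientation_mode="spiral"),
            dict(vessel_radius_um=(3.0, 2.0)),
            dict(pixel_size_um=0.0),
        ):
            with pytest.raises(ValueError):
                generate_scene(small_params(**bad))

    def test_aligned_zero_jitter_plants_only_vertical_segments(self):
        p = small_params(orientation_mode="aligned", orientation_jitter_deg=0.0,
                         orientation_axis_deg=90.0, secondary_prob=0.3)
        scene = generate_scene(p)
        angles = scene.segment_angles_deg()
        assert len(angles) > 0
        np.testing.assert_allclose(angles, 90.0, atol=1e-9)

    def test_isotropic_orientations_pass_rayleigh_uniformity(self):
        # pool planted segment orientations over seeds; doubled-angle
        # Rayleigh test must not reject circular uniformity at alpha=0.01
        angles = []
        for seed in range(25):
            p = SceneParams(field_size_um=(500.0, 500.0), seed=seed,
                            noise_sigma=0.0)
            angles.extend(generate_scene(p).segment_angles_deg())
        theta = 2.0 * np.radians(angles)  # orientations live on [0, pi)
        n = len(theta)
        assert n >= 1000
        rbar = math.hypot(np.cos(theta).sum(), np.sin(theta).sum()) / n
        z = n * rbar**2
        p_value = math.exp(-z) * (1 + (2 * z - z**2) / (4 * n))
        assert p_value > 0.01

    def test_all_object_centers_respect_border_margin(self):
        scene = generate_scene(small_params(seed=3))
        h, w = scene.params.field_size_um
        for s in scene.somata:
            assert MARGIN_UM <= s.center_um[0] <= h - MARGIN_UM
            assert MARGIN_UM <= s.center_um[1] <= w - MARGIN_UM
        for q in scene.puncta:
            assert MARGIN_UM <= q.center_um[0] <= h - MARGIN_UM
        for nb in scene.neurons:
            assert MARGIN_UM <= nb.center_um[1] <= w - MARGIN_UM

    def test_branch_topology_invariants(self):
        scene = generate_scene(small_params(seed=7, secondary_prob=0.5))
        h, w = scene.params.field_size_um
        for bi, b in enumerate(scene.branches):
            v = np.asarray(b.vertices_um)
            assert (v >= 0).all() and (v[:, 0] <= h).all() and (v[:, 1] <= w).all()
            if b.parent == -1:
                s = scene.somata[b.cell]
                d = math.hypot(v[0, 0] - s.center_um[0], v[0, 1] - s.center_um[1])
                assert d == pytest.approx(s.radius_um, abs=1e-9)
            else:
                parent = scene.branches[b.parent]
                (a0, a1) = np.asarray(parent.vertices_um)
                seg = a1 - a0
                t = np.dot(v[0] - a0, seg) / np.dot(seg, seg)
                foot = a0 + t * seg
                assert 0 <= t <= 1
                assert np.hypot(*(v[0] - foot)) < 1e-9

    def test_vessel_radii_and_punctum_areas_positive(self):
        scene = generate_scene(small_params(seed=9))
        assert all(r > 0 for v in scene.vessels for r in v.radii_um)
        assert all(q.area_um2 > 0 for q in scene.puncta)

    def test_planted_density_matches_request_within_poisson_error(self):
        # vessel length density is stochastic: expect within ~3 sd
        dens = []
        for seed in range(5):
            p = SceneParams(seed=seed, noise_sigma=0.0)
            sc = generate_scene(p)
            dens.append(sc.vessel_centerline_length_um() / sc.field_area_um2)
        assert np.mean(dens) == pytest.approx(0.003, rel=0.25)


class TestRender:
    def test_single_soma_peaks_at_center(self):
        p = small_params(blur_sigma_um=0.0)
        scene = GroundTruthScene(p, [Soma((150.0, 150.0), 6.0)], [], [], [], [],
                                 [[10.0, 0.0], [10.0, 300.0]], 0)
        img = render(scene, "astrocyte")
        cy = cx = int(150.0 / 1.0 - 0.5)
        assert img.pixels[cy, cx] == img.pixels.max() == 1.0

    def test_straight_tube_width_matches_radius(self):
        p = SceneParams(field_size_um=(50.0, 100.0), pixel_size_um=0.5,
                        seed=0, noise_sigma=0.0, blur_sigma_um=0.0)
        scene = GroundTruthScene(
            p, [], [], [Vessel(-1, [[25.0, 5.0], [25.0, 95.0]], [2.0, 2.0])],
            [], [], [[1.0, 0.0], [1.0, 100.0]], 0)  # radius 2 um = 4 px
        img = render(scene, "vessel")
        fg = img.pixels >= 0.5
        widths = fg[:, 40:160].sum(axis=0)
        assert set(widths.tolist()) <= {8, 9}

    def test_empty_channel_renders_pure_noise(self):
        p = small_params(noise_sigma=0.05, astrocyte_density_mm2=0.0)
        scene = generate_scene(p)
        img = render(scene, "astrocyte")
        assert img.pixels.max() <= 1.0 and img.pixels.min() >= 0.0
        assert 0 < (img.pixels > 0).mean() < 0.9  # clipped noise, no objects

    def test_translation_equivariance_by_whole_pixels(self):
        p = small_params(blur_sigma_um=0.0)
        base = GroundTruthScene(p, [Soma((100.0, 120.0), 5.0)], [], [], [], [],
                                [[10.0, 0.0], [10.0, 300.0]], 0)
        shifted = GroundTruthScene(p, [Soma((107.0, 117.0), 5.0)], [], [], [], [],
                                   [[10.0, 0.0], [10.0, 300.0]], 0)
        a = render(base, "astrocyte").pixels
        b = render(shifted, "astrocyte").pixels
        np.testing.assert_array_equal(a[80:120, 100:140], b[87:127, 97:137])

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError):
            render(generate_scene(small_params()), "mitochondria")


class TestSerialization:
    def test_scene_json_round_trip(self):
        scene = generate_scene(small_params(seed=13))
        clone = GroundTruthScene.from_dict(json.loads(json.dumps(scene.to_dict())))
        assert clone.to_dict() == scene.to_dict()
        np.testing.assert_array_equal(
            render(clone, "vessel").pixels, render(scene, "vessel").pixels
        )

    def test_save_writes_truth_json_and_channel_tiffs(self, tmp_path):
        import tifffile

        scene = generate_scene(small_params(seed=2))
        scene.save(tmp_path)
        assert (tmp_path / "scene.json").exists()
        arr = tifffile.imread(tmp_path / "astrocyte.tif")
        np.testing.assert_allclose(
            arr, render(scene, "astrocyte").pixels.astype(np.float32), atol=0
        )
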
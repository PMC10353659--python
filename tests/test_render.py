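"""Pinhole projection, rasterized rendering, and label fidelity."""

import math

import numpy as np
import pytest

from gfseg import canopy_sim as cs
from gfseg import evaluate as ev
from gfseg import render as rn

from conftest import clean_camera, clean_light


def nadir_cam(res=1024, fov=85.0, h=1.5):
    return rn.CameraConfig(height=h, fov=fov, inclination=0.0, resolution=res)


def plane_scene(half=5.0, z=0.01, crop_bg="soil"):
    """One large horizontal square (two triangles) hovering above ground."""
    quad = np.array([
        [[-half, -half, z], [half, -half, z], [half, half, z]],
        [[-half, -half, z], [half, half, z], [-half, half, z]],
    ])
    return cs.Scene(quad, [cs.GREEN_VEGETATION] * 2,
                    cs.Background(kind=crop_bg), (2 * half, 2 * half))


class TestProject:
    def test_optical_axis_hits_image_center(self):
        cam = rn.CameraConfig(height=1.5, fov=60, inclination=30, resolution=512)
        pos, _, _, fwd = cam.basis()
        point = pos + 0.7 * fwd
        assert rn.project(point, cam) == pytest.approx((256.0, 256.0))

    def test_fov_edge_maps_to_frame_edge(self):
        cam = nadir_cam()
        x = 1.5 * math.tan(math.radians(85 / 2))
        u, v = rn.project((x, 0, 0), cam)
        assert u == pytest.approx(1024.0)
        assert v == pytest.approx(512.0)

    def test_closed_form_offaxis_oracle(self):
        # nadir h=1.5, fov=85, res=1024, ground point 0.5 m off-axis
        cam = nadir_cam()
        u, v = rn.project((0.5, 0.0, 0.0), cam)
        expected = 512 + 512 * (0.5 / 1.5) / math.tan(math.radians(42.5))
        assert u == pytest.approx(expected, abs=1e-9)
        assert v == pytest.approx(512.0)

    def test_point_behind_camera(self):
        assert rn.project((0, 0, 3.0), nadir_cam()) is None

    def test_camera_origin_rejected(self):
        with pytest.raises(ValueError):
            rn.project((0, 0, 1.5), nadir_cam())

    def test_outside_frustum_outside_frame(self):
        cam = nadir_cam()
        u, v = rn.project((10.0, 0, 0), cam)
        assert u > 1024


class TestGroundSampleDistance:
    def test_stated_formula_value(self):
        assert rn.ground_sample_distance(nadir_cam()) == pytest.approx(2.6846, abs=1e-3)

    def test_resolution_halves_gsd(self):
        g1 = rn.ground_sample_distance(nadir_cam(res=512))
        g2 = rn.ground_sample_distance(nadir_cam(res=1024))
        assert g1 == pytest.approx(2 * g2)

    def test_inclination_60_doubles_gsd(self):
        flat = rn.ground_sample_distance(nadir_cam())
        tilted = rn.ground_sample_distance(
            rn.CameraConfig(height=1.5, fov=85, inclination=60, resolution=1024))
        assert tilted == pytest.approx(2 * flat)

    def test_grazing_rejected(self):
        with pytest.raises(ValueError):
            rn.CameraConfig(height=1.5, fov=85, inclination=95, resolution=64)


class TestLightConfig:
    def test_sunny_requires_direct_dominance(self):
        with pytest.raises(ValueError):
            rn.LightConfig(condition="sunny", diffuse_fraction=0.7)

    def test_cloudy_requires_diffuse_dominance(self):
        with pytest.raises(ValueError):
            rn.LightConfig(condition="cloudy", diffuse_fraction=0.5)


class TestRenderSample:
    def test_empty_scene_all_background(self):
        scene = cs.Scene(np.empty((0, 3, 3)), [], cs.Background("soil"), (1, 1))
        s = rn.render_sample(scene, clean_camera(64), clean_light(), seed=0)
        assert not s.mask.any()
        assert ev.green_fraction(s.mask) == 0.0

    def test_full_cover_leaf_all_green(self):
        s = rn.render_sample(plane_scene(), clean_camera(64), clean_light(), seed=0)
        assert s.mask.all()
        assert ev.green_fraction(s.mask) == 1.0

    def test_unit_square_coverage_vs_rasterization_oracle(self):
        # mask pixel count vs brute-force pixel-center point-in-square test
        cam = rn.CameraConfig(height=2.0, fov=60, inclination=0, resolution=128)
        half = 0.5
        quad = np.array([
            [[-half, -half, 0.01], [half, -half, 0.01], [half, half, 0.01]],
            [[-half, -half, 0.01], [half, half, 0.01], [-half, half, 0.01]],
        ])
        scene = cs.Scene(quad, [cs.GREEN_VEGETATION] * 2, cs.Background("soil"), (1, 1))
        s = rn.render_sample(scene, cam, clean_light(), seed=0)

        # oracle: project every pixel center ray onto the z=0.01 plane
        res, f = 128, cam.focal_px
        jj, ii = np.mgrid[0:res, 0:res]
        xn = (ii + 0.5 - res / 2) / f
        yn = (jj + 0.5 - res / 2) / f
        # nadir: ray (xn, yn, -1) from (0,0,2) hits z=0.01 at t=1.99
        gx = xn * 1.99
        gy = yn * 1.99
        inside = (np.abs(gx) <= half) & (np.abs(gy) <= half)
        perimeter_px = 4 * (2 * half / (1.99 / f))
        assert abs(int(s.mask.sum()) - int(inside.sum())) <= perimeter_px

    def test_bit_identical_determinism(self, small_scene):
        a = rn.render_sample(small_scene, clean_camera(128), clean_light(), seed=9)
        b = rn.render_sample(small_scene, clean_camera(128), clean_light(), seed=9)
        np.testing.assert_array_equal(a.rgb, b.rgb)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_seed_changes_pixels_not_mask(self, small_scene):
        a = rn.render_sample(small_scene, clean_camera(128), clean_light(), seed=1)
        b = rn.render_sample(small_scene, clean_camera(128), clean_light(), seed=2)
        assert not np.array_equal(a.rgb, b.rgb)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_light_never_changes_labels(self, small_scene):
        cam = clean_camera(128)
        sunny = rn.render_sample(small_scene, cam,
                                 rn.LightConfig(condition="sunny", shadows=True), seed=4)
        cloudy = rn.render_sample(small_scene, cam,
                                  rn.LightConfig(condition="cloudy", diffuse_fraction=0.9,
                                                 shadows=False), seed=4)
        assert not np.array_equal(sunny.rgb, cloudy.rgb)
        np.testing.assert_array_equal(sunny.mask, cloudy.mask)

    def test_adding_green_triangle_monotone_mask(self, small_scene):
        cam = clean_camera(128)
        light = clean_light()
        base = rn.render_sample(small_scene, cam, light, seed=0).mask
        extra = np.concatenate([small_scene.triangles,
                                plane_scene(half=0.15, z=0.5).triangles])
        grown = cs.Scene(extra, [cs.GREEN_VEGETATION] * len(extra),
                         small_scene.background, small_scene.plot_extent)
        grown_mask = rn.render_sample(grown, cam, light, seed=0).mask
        assert not (base & ~grown_mask).any()  # green never reverts

    def test_mask_strictly_two_valued_and_aligned(self, clean_sample):
        assert clean_sample.mask.dtype == bool
        assert clean_sample.rgb.shape[:2] == clean_sample.mask.shape
        assert clean_sample.meta["green_pixel_count"] == int(clean_sample.mask.sum())

    def test_water_background_renders_light_gray(self):
        scene = cs.Scene(np.empty((0, 3, 3)), [], cs.Background("water"), (1, 1))
        s = rn.render_sample(scene, clean_camera(64), clean_light(), seed=0)
        r, g, b = s.rgb.reshape(-1, 3).mean(axis=0)
        assert abs(int(r) - int(g)) < 8 and abs(int(g) - int(b)) < 12
        assert g > 100  # light, not dark

    def test_sunny_shadows_darken_some_background(self, small_scene):
        cam = clean_camera(128)
        with_sh = rn.render_sample(
            small_scene, cam, rn.LightConfig(condition="sunny", shadows=True), seed=6)
        without = rn.render_sample(
            small_scene, cam, rn.LightConfig(condition="sunny", shadows=False), seed=6)
        bg = ~with_sh.mask
        assert (with_sh.rgb[bg].astype(int).sum(axis=1)
                < without.rgb[bg].astype(int).sum(axis=1) - 10).any()

    def test_meta_round_trips_through_disk(self, tmp_path, clean_sample):
        rn.write_sample(clean_sample, tmp_path, "s0")
        back = rn.read_sample(tmp_path, "s0")
        np.testing.assert_array_equal(back.rgb, clean_sample.rgb)
        np.testing.assert_array_equal(back.mask, clean_sample.mask)
        assert back.meta == clean_sample.meta
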
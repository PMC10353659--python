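"""Parameter-space sampling and canopy geometry."""

import dataclasses
import math

import numpy as np
import pytest

from gfseg import canopy_sim as cs

from conftest import small_params


def unit_space(n_dims=1, n_stages=1):
    dims = tuple(cs.Dim(name, 0.0, 1.0) for name in
                 ["plant_jitter", "leaf_hue", "leaf_saturation"][:n_dims])
    return cs.ParameterSpace(dims=dims, crop="wheat", n_stages=n_stages)


class TestParameterSpace:
    def test_rejects_inverted_bounds(self):
        with pytest.raises(ValueError, match="low < high"):
            cs.Dim("plant_density", 5.0, 5.0)

    def test_rejects_duplicate_names(self):
        d = cs.Dim("leaf_hue", 0.0, 1.0)
        with pytest.raises(ValueError, match="unique"):
            cs.ParameterSpace(dims=(d, d), crop="rice")

    def test_rejects_unknown_dimension(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            cs.ParameterSpace(dims=(cs.Dim("wingspan", 0, 1),), crop="rice")

    def test_rejects_zero_stages(self):
        with pytest.raises(ValueError, match="n_stages"):
            cs.ParameterSpace(dims=(cs.Dim("leaf_hue", 0, 1),), crop="rice", n_stages=0)

    def test_yaml_round_trip(self, tmp_path):
        space = cs.default_space("rice", 4)
        path = tmp_path / "space.yaml"
        import yaml

        path.write_text(yaml.safe_dump(space.to_dict()))
        assert cs.ParameterSpace.from_yaml(path) == space


class TestLatinHypercube:
    def test_empty_draw(self):
        assert cs.sample_parameter_space(unit_space(), 0, seed=1) == []

    def test_negative_draw_rejected(self):
        with pytest.raises(ValueError):
            cs.sample_parameter_space(unit_space(), -1, seed=1)

    def test_four_samples_fill_four_strata(self):
        pts = cs.sample_parameter_space(unit_space(), 4, seed=3)
        strata = sorted(int(p.plant_jitter * 4) for p in pts)
        assert strata == [0, 1, 2, 3]

    @pytest.mark.parametrize("n", [1, 5, 16, 64])
    def test_one_point_per_stratum_every_dim(self, n):
        # marginal LHS property across many seeds
        space = unit_space(n_dims=3)
        for seed in range(100):
            pts = cs.sample_parameter_space(space, n, seed=seed)
            for name in ("plant_jitter", "leaf_hue", "leaf_saturation"):
                occupied = sorted(min(int(getattr(p, name) * n), n - 1) for p in pts)
                assert occupied == list(range(n))

    def test_log_scale_stratifies_in_log_space(self):
        space = cs.ParameterSpace(
            dims=(cs.Dim("plant_density", 1.0, 10000.0, scale="log"),),
            crop="wheat", n_stages=1)
        pts = cs.sample_parameter_space(space, 4, seed=7)
        strata = sorted(int(math.log10(p.plant_density)) for p in pts)
        assert strata == [0, 1, 2, 3]

    def test_deterministic_given_seed(self):
        space = cs.default_space("wheat")
        a = cs.sample_parameter_space(space, 8, seed=42)
        b = cs.sample_parameter_space(space, 8, seed=42)
        assert a == b
        c = cs.sample_parameter_space(space, 8, seed=43)
        assert a != c

    def test_paper_scale_pairing(self):
        # 500 sampled points replicated over 4 growth stages -> 2,000 specs
        space = cs.default_space("rice", n_stages=4)
        pts = cs.sample_parameter_space(space, 500, seed=0)
        specs = cs.expand_stages(pts)
        assert len(specs) == 2000
        assert {p.growth_stage for p in specs} == {1, 2, 3, 4}


class TestLeafSurface:
    def test_vertical_straight_limit(self):
        tris = cs.leaf_surface(0.2, 0.01, inclination=90, curvature=0,
                               azimuth=30, base=(0, 0, 0.1))
        assert tris[..., 2].max() == pytest.approx(0.1 + 0.2)
        # planar strip: all x/y stay within half the max width of the base
        assert np.abs(tris[..., :2]).max() <= 0.005 + 1e-12

    def test_horizontal_limit_projected_area(self):
        tris = cs.leaf_surface(0.2, 0.012, inclination=0, curvature=0,
                               azimuth=0, base=(0, 0, 0))
        assert np.allclose(tris[..., 2], 0.0)
        nadir = 0.5 * np.abs(np.cross(tris[:, 1] - tris[:, 0],
                                      tris[:, 2] - tris[:, 0])[:, 2]).sum()
        area = 0.5 * np.linalg.norm(np.cross(tris[:, 1] - tris[:, 0],
                                             tris[:, 2] - tris[:, 0]), axis=1).sum()
        assert nadir == pytest.approx(area)

    def test_mesh_area_matches_analytic_strip(self):
        L, W = 0.25, 0.014
        tris = cs.leaf_surface(L, W, inclination=50, curvature=1.5,
                               azimuth=120, base=(0, 0, 0.5))
        area = 0.5 * np.linalg.norm(np.cross(tris[:, 1] - tris[:, 0],
                                             tris[:, 2] - tris[:, 0]), axis=1).sum()
        assert area == pytest.approx(0.5 * L * W, rel=0.05)
        assert len(tris) >= 16  # >= 8 segments, 2 triangles each

    def test_strong_curvature_droops_tip_below_base(self):
        # oracle: integrate the tangent-angle ODE d(theta)/ds = -c*(pi/2)/L
        L, c, theta0 = 0.2, 3.0, math.radians(45)
        s = np.linspace(0, L, 20001)
        theta = theta0 - c * (math.pi / 2) * s / L
        z_oracle = np.trapezoid(np.sin(theta), s)
        tris = cs.leaf_surface(L, 0.01, inclination=45, curvature=c,
                               azimuth=0, base=(0, 0, 1.0))
        tip_z = tris[-1][2, 2] - 1.0  # last row collapses to the tip point
        assert z_oracle < 0
        assert tip_z == pytest.approx(z_oracle, abs=1e-3)
        assert tip_z < 0

    def test_rejects_degenerate_geometry(self):
        with pytest.raises(ValueError):
            cs.leaf_surface(0.0, 0.01, 45, 0, 0, (0, 0, 0))
        with pytest.raises(ValueError):
            cs.leaf_surface(0.2, -0.01, 45, 0, 0, (0, 0, 0))


class TestBuildCanopy:
    def test_zero_density_gives_empty_scene(self):
        scene = cs.build_canopy(small_params(plant_density=0.0))
        assert scene.n_triangles == 0
        assert scene.total_area() == 0.0

    def test_realized_leaf_count_oracle(self):
        # 100 plants/m2 on a 1 m x 1 m plot, 1 tiller x 1 leaf -> 100 leaves
        p = small_params(plant_density=100.0, tillers_per_plant=1,
                         leaves_per_tiller=1, growth_stage=2, n_stages=2)
        scene = cs.build_canopy(p, plot_extent=(1.0, 1.0))
        tris_per_leaf = len(cs.leaf_surface(0.1, 0.01, 45, 0, 0, (0, 0, 0)))
        assert scene.n_triangles == 100 * tris_per_leaf

    def test_zero_curvature_midribs_collinear(self):
        p = small_params(leaf_curvature=0.0, plant_jitter=0.0,
                         tillers_per_plant=1, leaves_per_tiller=1,
                         plant_density=4.0)
        scene = cs.build_canopy(p, plot_extent=(1.0, 1.0))
        # each leaf is a straight strip: its triangle normals all agree
        per_leaf = scene.triangles.reshape(4, -1, 3, 3)
        for leaf in per_leaf:
            n = np.cross(leaf[:, 1] - leaf[:, 0], leaf[:, 2] - leaf[:, 0])
            n = n[np.linalg.norm(n, axis=1) > 1e-15]
            n /= np.linalg.norm(n, axis=1, keepdims=True)
            assert np.abs(n @ n[0]).min() > 1 - 1e-9

    def test_deterministic(self):
        p = small_params(seed=5)
        a = cs.build_canopy(p)
        b = cs.build_canopy(p)
        np.testing.assert_array_equal(a.triangles, b.triangles)
        np.testing.assert_array_equal(a.leaf_colors, b.leaf_colors)

    def test_density_doubling_never_shrinks_leaf_area(self):
        for seed in range(5):
            for dens in (10.0, 25.0, 60.0):
                lo = cs.build_canopy(small_params(plant_density=dens, seed=seed))
                hi = cs.build_canopy(small_params(plant_density=2 * dens, seed=seed))
                assert hi.total_area() >= lo.total_area()

    def test_leaf_area_nondecreasing_in_growth_stage(self):
        for seed in range(5):
            areas = []
            for stage in (1, 2, 3, 4):
                p = small_params(seed=seed, growth_stage=stage, n_stages=4,
                                 leaf_curvature=1.2)
                areas.append(cs.build_canopy(p).total_area())
            assert all(b >= a for a, b in zip(areas, areas[1:]))

    def test_background_matches_crop(self):
        assert cs.build_canopy(small_params(crop="rice")).background.kind == "water"
        assert cs.build_canopy(small_params(crop="wheat")).background.kind == "soil"

    def test_all_triangles_above_ground(self, small_scene):
        assert small_scene.triangles[..., 2].min() >= 0.0

    def test_scene_json_round_trip(self, tmp_path, small_scene):
        path = tmp_path / "scene.json"
        small_scene.to_json(path)
        back = cs.Scene.from_json(path)
        np.testing.assert_allclose(back.triangles, small_scene.triangles)
        assert back.background == small_scene.background
        assert back.plot_extent == tuple(small_scene.plot_extent)
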
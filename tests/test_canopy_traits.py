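"""Ground plane, heights, segmentation, occupancy and the two LAI routes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fieldpheno.canopy_traits import (
    LABEL_CROP,
    LABEL_SOIL,
    LABEL_WEED,
    GroundPlane,
    OccupancyGrid,
    PlantPointCloud,
    fit_ground_plane,
    gap_fraction,
    growth_rate,
    lai_from_gap,
    leaf_area_lai,
    orthographic_occupancy,
    plant_height,
    plot_height,
    segment_canopy,
)
from fieldpheno.errors import (
    InvalidParameterError,
    NoPlaneError,
    NoPlantError,
    SaturatedCanopyError,
)
from fieldpheno.synthetic_field import make_plant, make_plot_scene


class TestGroundPlane:
    def test_perfect_plane(self, rng):
        pts = np.column_stack([rng.uniform(-1, 1, (200, 2)), np.zeros(200)])
        plane = fit_ground_plane(PlantPointCloud(pts))
        assert plane.normal == pytest.approx([0, 0, 1], abs=1e-9)
        assert plane.offset == pytest.approx(0.0, abs=1e-9)
        assert plane.inlier_fraction == 1.0

    def test_plane_with_canopy_outliers(self, rng):
        ground = np.column_stack([rng.uniform(-1, 1, (700, 2)), np.zeros(700)])
        canopy = np.column_stack(
            [rng.uniform(-1, 1, (300, 2)), rng.uniform(0.5, 2.0, 300)]
        )
        plane = fit_ground_plane(PlantPointCloud(np.vstack([ground, canopy])))
        assert abs(plane.offset) < 1e-3
        assert plane.normal[2] > 0.9999

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(3.0), np.arange(3.0), np.zeros(3)])
        with pytest.raises(NoPlaneError):
            fit_ground_plane(PlantPointCloud(pts))

    def test_tilted_field_recovered(self, rng):
        # 5-degree slope: heights must still be perpendicular distances
        xy = rng.uniform(-1, 1, (500, 2))
        z = np.tan(np.deg2rad(5)) * xy[:, 0]
        plane = fit_ground_plane(PlantPointCloud(np.column_stack([xy, z])))
        expected = np.array([-np.sin(np.deg2rad(5)), 0, np.cos(np.deg2rad(5))])
        assert plane.normal == pytest.approx(expected, abs=1e-6)


class TestPlantHeight:
    def test_annotated_mode_is_perpendicular_distance(self):
        plane = GroundPlane([0.0, 0.0, 1.0], 0.0)
        cloud = PlantPointCloud(np.array([[0.0, 0.0, 0.5]]))
        h = plant_height(cloud, plane, mode="annotated",
                         collar_point=[3.0, -2.0, 1.234])
        assert h == pytest.approx(1.234)

    def test_auto_mode_recovers_generator_collar(self):
        plane = GroundPlane([0.0, 0.0, 1.0], 0.0)
        for seed in range(5):
            cloud, gt = make_plant(collar_height=0.80, seed=seed)
            h = plant_height(cloud, plane, mode="auto")
            assert h == pytest.approx(0.80, abs=0.01)

    def test_cloud_below_plane_is_no_plant(self):
        plane = GroundPlane([0.0, 0.0, 1.0], 5.0)
        cloud = PlantPointCloud(np.array([[0.0, 0.0, 0.5]]))
        with pytest.raises(NoPlantError):
            plant_height(cloud, plane, mode="auto")


class TestPlotHeight:
    def test_mean_of_two(self):
        plane = GroundPlane([0.0, 0.0, 1.0], 0.0)
        out = plot_height([1.0, 1.2], plane)
        assert out["mean"] == pytest.approx(1.1)

    def test_identical_plants_zero_sd(self):
        out = plot_height([0.8] * 10)
        assert out["mean"] == pytest.approx(0.8)
        assert out["sd"] == 0.0

    def test_matches_direct_mean_of_generator_draws(self, plot_scene,
                                                    plot_ground):
        cloud, gt = plot_scene
        clouds = [cloud.select(gt.plant_index == i) for i in range(10)]
        out = plot_height(clouds, plot_ground, mode="auto")
        assert out["mean"] == pytest.approx(gt.collar_heights.mean(), abs=0.01)
        assert out["n"] == 10


class TestGrowthRate:
    def test_two_point_slope(self):
        fit = growth_rate([(10, 0.1), (20, 0.3)])
        assert fit["slope"] == pytest.approx(0.02)

    def test_constant_heights(self):
        fit = growth_rate([(10, 0.5), (20, 0.5), (30, 0.5)])
        assert fit["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_ols(self, rng):
        dap = np.arange(8, dtype=float) * 5 + 10
        h = 0.02 * dap + 0.05 + rng.normal(0, 0.01, 8)
        fit = growth_rate(list(zip(dap, h)))
        # closed-form OLS slope
        sxy = np.sum((dap - dap.mean()) * (h - h.mean()))
        sxx = np.sum((dap - dap.mean()) ** 2)
        assert fit["slope"] == pytest.approx(sxy / sxx, abs=1e-12)
        assert fit["intercept"] == pytest.approx(h.mean() - sxy / sxx * dap.mean(),
                                                 abs=1e-12)

    def test_single_time_point_rejected(self):
        with pytest.raises(InvalidParameterError):
            growth_rate([(10, 0.1)])


class TestSegmentation:
    def test_pure_soil_cloud(self, rng):
        pts = np.column_stack([rng.uniform(0, 1, (100, 2)), np.zeros(100)])
        colors = np.tile([120, 84, 50], (100, 1)).astype(np.uint8)
        plane = GroundPlane([0.0, 0.0, 1.0], 0.0)
        labeled, info = segment_canopy(PlantPointCloud(pts, colors), plane)
        assert info["n_crop"] == 0
        assert info["no_green"]  # warning flag, not an error
        assert np.all(labeled.labels == LABEL_SOIL)

    def test_crop_and_weed_split_matches_generator(self):
        # crop canopy at 1.0 m, weed layer at 0.1 m, fixed 0.3 m threshold
        rng = np.random.default_rng(3)
        n = 500
        crop = np.column_stack([rng.uniform(0, 1, (n, 2)),
                                rng.uniform(0.9, 1.1, n)])
        weed = np.column_stack([rng.uniform(0, 1, (n, 2)),
                                rng.uniform(0.0, 0.2, n)])
        soil = np.column_stack([rng.uniform(0, 1, (n, 2)), np.zeros(n)])
        green = np.tile([40, 150, 40], (2 * n, 1))
        brown = np.tile([120, 84, 50], (n, 1))
        cloud = PlantPointCloud(
            np.vstack([crop, weed, soil]),
            np.vstack([green, brown]).astype(np.uint8),
        )
        plane = GroundPlane([0.0, 0.0, 1.0], 0.0)
        labeled, info = segment_canopy(cloud, plane, height_threshold=0.3)
        expected = np.concatenate(
            [np.full(n, LABEL_CROP), np.full(n, LABEL_WEED),
             np.full(n, LABEL_SOIL)]
        )
        assert np.array_equal(labeled.labels, expected)

    def test_all_green_above_threshold_no_weeds(self, rng):
        pts = np.column_stack([rng.uniform(0, 1, (100, 2)),
                               rng.uniform(0.5, 1.0, 100)])
        colors = np.tile([40, 150, 40], (100, 1)).astype(np.uint8)
        plane = GroundPlane([0.0, 0.0, 1.0], 0.0)
        _, info = segment_canopy(PlantPointCloud(pts, colors), plane)
        assert info["n_weed"] == 0

    def test_auto_threshold_separates_bimodal_heights(self):
        cloud, gt = make_plot_scene(seed=8)[0], make_plot_scene(seed=8)[1]
        plane = fit_ground_plane(cloud)
        labeled, info = segment_canopy(cloud, plane, height_threshold="auto")
        assert 0.05 < info["height_threshold"] < 0.9
        crop_sel = labeled.labels == LABEL_CROP
        assert (gt.labels[crop_sel] == LABEL_CROP).mean() > 0.95


class TestOccupancyAndGapFraction:
    def test_single_point_single_cell(self):
        cloud = PlantPointCloud(np.array([[0.505, 0.505, 1.0]]))
        grid = orthographic_occupancy(cloud, (0, 0, 1, 1), 0.01)
        assert grid.grid.sum() == 1
        assert grid.grid[50, 50]

    def test_empty_roi_flagged(self):
        cloud = PlantPointCloud(np.array([[5.0, 5.0, 1.0]]))
        grid = orthographic_occupancy(cloud, (0, 0, 1, 1), 0.01)
        assert grid.empty_roi and grid.grid.sum() == 0

    def test_matches_brute_force_binning(self, rng):
        pts = np.column_stack([rng.uniform(-0.2, 1.2, (10000, 2)),
                               rng.uniform(0, 2, 10000)])
        cloud = PlantPointCloud(pts)
        cell = 0.05
        grid = orthographic_occupancy(cloud, (0, 0, 1, 1), cell)
        oracle = np.zeros_like(grid.grid)
        for x, y, _ in pts:
            if 0 <= x < 1 and 0 <= y < 1:
                oracle[min(int(y / cell), 19), min(int(x / cell), 19)] = True
        assert np.array_equal(grid.grid, oracle)

    def test_gap_fraction_complement_identity(self, rng):
        for _ in range(10):
            g = rng.random((20, 30)) < rng.random()
            grid = OccupancyGrid(g, 0.01, (0, 0), (0.30, 0.20))
            assert gap_fraction(grid) + g.mean() == pytest.approx(1.0)


class TestLai:
    def test_gap_lai_closed_forms(self):
        assert lai_from_gap(1.0) == 0.0
        assert lai_from_gap(np.exp(-1.0)) == pytest.approx(2.0, abs=1e-12)
        assert lai_from_gap(0.75) == pytest.approx(0.5753641449035618, abs=1e-12)

    def test_gap_lai_strictly_decreasing(self):
        p = np.linspace(0.01, 1.0, 200)
        lai = np.array([lai_from_gap(x) for x in p])
        assert np.all(np.diff(lai) < 0)

    def test_saturated_and_invalid_gap(self):
        with pytest.raises(SaturatedCanopyError):
            lai_from_gap(0.0)
        with pytest.raises(InvalidParameterError):
            lai_from_gap(1.5)

    def test_leafsum_arithmetic(self):
        assert leaf_area_lai([0.03, 0.03], 0.3) == pytest.approx(0.2)
        assert leaf_area_lai([], 0.3) == 0.0

    def test_leafsum_from_triangulated_patches(self):
        # two unit right triangles forming a 1x1 square
        tris = np.array([
            [[0, 0, 0], [1, 0, 0], [1, 1, 0]],
            [[0, 0, 0], [1, 1, 0], [0, 1, 0]],
        ], dtype=float)
        assert leaf_area_lai([tris], 2.0) == pytest.approx(0.5)

    def test_mesh_lai_within_1pct_of_analytic(self):
        _, gt = make_plant(seed=4)
        meshes = [leaf.mesh(24) for leaf in gt.leaves]
        lai_mesh = leaf_area_lai(meshes, 1.0)
        assert lai_mesh == pytest.approx(gt.total_leaf_area, rel=0.01)

    def test_invalid_ground_area(self):
        with pytest.raises(InvalidParameterError):
            leaf_area_lai([0.1], 0.0)


@given(st.integers(0, 599), st.integers(1, 600))
@settings(max_examples=30, deadline=None)
def test_gap_fraction_equals_count_ratio(n_fg, total):
    """P0 is exactly the background/total cell ratio for any fill level."""
    if n_fg > total:
        n_fg = total
    g = np.zeros(total, dtype=bool)
    g[:n_fg] = True
    rows = 1
    grid = OccupancyGrid(g.reshape(rows, total), 0.01, (0, 0),
                         (total * 0.01, 0.01))
    assert gap_fraction(grid) == pytest.approx((total - n_fg) / total)
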
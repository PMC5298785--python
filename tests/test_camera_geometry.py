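"""Projection model, triangulation, planar calibration and error reporting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from fieldpheno.camera_geometry import (
    CameraIntrinsics,
    RigidTransform,
    calibrate_planar,
    estimate_rig_extrinsics,
    project_point,
    project_points,
    reprojection_error_report,
    triangulate_pair,
    undistort_pixel,
    undistort_pixels,
)
from fieldpheno.errors import (
    BehindCameraError,
    DegenerateGeometryError,
    InsufficientViewsError,
    InvalidParameterError,
    NoCorrespondencesError,
)
from fieldpheno.synthetic_field import default_rig, render_board_views


def cam(fx=1000.0, fy=1000.0, cx=960.0, cy=600.0, dist=(0, 0, 0, 0, 0)):
    return CameraIntrinsics(fx, fy, cx, cy, dist=np.asarray(dist, float),
                            image_size=(1920, 1200))


class TestProjection:
    def test_optical_axis_maps_to_principal_point(self):
        c = cam()
        assert project_point([0.0, 0.0, 2.0], c) == pytest.approx([960.0, 600.0])

    def test_pinhole_u_formula(self):
        c = cam()
        u, v = project_point([0.5, 0.0, 1.0], c)
        assert u == pytest.approx(1000 * 0.5 + 960)
        assert v == pytest.approx(600.0)

    def test_radial_distortion_matches_hand_evaluation(self):
        # x = 0.5, r^2 = 0.25, radial factor = 1 + 0.1*0.25 = 1.025
        c = cam(dist=(0.1, 0, 0, 0, 0))
        u, v = project_point([0.5, 0.0, 1.0], c)
        assert u == pytest.approx(1000 * 0.5 * 1.025 + 960, abs=1e-9)
        assert v == pytest.approx(600.0, abs=1e-9)

    def test_full_distortion_polynomial_hand_evaluation(self):
        k1, k2, p1, p2, k3 = 0.1, -0.02, 0.001, -0.002, 0.005
        c = cam(dist=(k1, k2, p1, p2, k3))
        x, y = 0.3, -0.2
        r2 = x * x + y * y
        radial = 1 + k1 * r2 + k2 * r2**2 + k3 * r2**3
        xd = x * radial + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
        yd = y * radial + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
        u, v = project_point([x * 2.0, y * 2.0, 2.0], c)
        assert u == pytest.approx(1000 * xd + 960, abs=1e-12)
        assert v == pytest.approx(1000 * yd + 600, abs=1e-12)

    def test_point_behind_camera_rejected(self):
        with pytest.raises(BehindCameraError):
            project_point([0.0, 0.0, -1.0], cam())

    def test_skew_enters_u_only(self):
        c = CameraIntrinsics(1000, 1000, 960, 600, skew=30.0,
                             image_size=(1920, 1200))
        u, v = project_point([0.0, 0.4, 1.0], c)
        assert u == pytest.approx(960 + 30 * 0.4)
        assert v == pytest.approx(600 + 1000 * 0.4)


class TestUndistort:
    def test_zero_distortion_is_linear_inverse(self):
        c = cam()
        xy = undistort_pixel([1460.0, 600.0], c)
        assert xy == pytest.approx([0.5, 0.0])

    def test_round_trip_through_projection(self, rng):
        c = cam(dist=(-0.2, 0.05, 0.001, -0.001, 0.01))
        pts = np.column_stack(
            [rng.uniform(-0.6, 0.6, 1000), rng.uniform(-0.35, 0.35, 1000),
             np.ones(1000)]
        )
        px = project_points(pts, c)
        xy = undistort_pixels(px, c)
        back = project_points(np.column_stack([xy, np.ones(len(xy))]), c)
        assert np.abs(back - px).max() < 1e-6

    def test_strong_barrel_matches_grid_search_oracle(self):
        # dense grid over normalized coordinates as an independent inverse
        c = cam(dist=(-0.2, 0, 0, 0, 0))
        target_px = np.array([1355.0, 480.0])
        grid = np.linspace(-0.8, 0.8, 4001)
        gx, gy = np.meshgrid(grid, grid[::8])
        pts = np.column_stack([gx.ravel(), gy.ravel(), np.ones(gx.size)])
        px = project_points(pts, c)
        best = np.argmin(np.sum((px - target_px) ** 2, axis=1))
        oracle = pts[best, :2]
        xy = undistort_pixel(target_px, c)
        assert np.abs(xy - oracle).max() < 1e-3  # grid resolution limited

    def test_recovered_ray_passes_through_source_point(self):
        c = cam(dist=(0.1, 0, 0, 0, 0))
        p = np.array([0.4, -0.3, 2.5])
        xy = undistort_pixel(project_point(p, c), c)
        assert np.allclose(xy, p[:2] / p[2], atol=1e-9)


class TestTriangulation:
    def test_noiseless_round_trip(self, rig, rng):
        pts = np.column_stack(
            [rng.uniform(-1, 2.5, 50), rng.uniform(-1.5, 1.5, 50),
             rng.uniform(3, 10, 50)]
        )
        pl = project_points(pts, rig.left)
        pr = project_points(rig.T_right_from_left.apply(pts), rig.right)
        rec = np.array([triangulate_pair(a, b, rig) for a, b in zip(pl, pr)])
        assert np.abs(rec - pts).max() < 1e-9

    def test_parallel_rays_are_degenerate(self, rig):
        px = [960.0, 600.0]
        with pytest.raises(DegenerateGeometryError):
            triangulate_pair(px, px, rig)

    def test_depth_noise_follows_stereo_propagation(self, rig, rng):
        """sigma_z ~= z^2 sigma_d / (f b) for 1 px noise at 10 m depth."""
        pt = np.array([rig.baseline / 2, 0.0, 10.0])
        pl = project_point(pt, rig.left)
        pr = project_point(rig.T_right_from_left.apply(pt), rig.right)
        z = [
            triangulate_pair(pl + rng.normal(0, 1, 2), pr + rng.normal(0, 1, 2),
                             rig)[2]
            for _ in range(1000)
        ]
        predicted = 10.0**2 * np.sqrt(2.0) / (rig.left.fx * rig.baseline)
        assert np.std(z) == pytest.approx(predicted, rel=0.25)


class TestCalibration:
    def test_noiseless_recovery_of_generator_intrinsics(self, board,
                                                        noiseless_views):
        obs, _ = noiseless_views
        c, poses, rms = calibrate_planar(obs["left"], board,
                                         image_size=(1920, 1200))
        assert c.fx == pytest.approx(1200.0, rel=1e-3)
        assert c.fy == pytest.approx(1200.0, rel=1e-3)
        assert c.cx == pytest.approx(960.0, rel=1e-3)
        assert c.cy == pytest.approx(600.0, rel=1e-3)
        assert rms <= 1e-6

    def test_injected_k1_recovered(self, board):
        rig = default_rig(rgb_dist=(-0.1, 0, 0, 0, 0))
        obs, _ = render_board_views(board, rig, n_views=10, seed=3)
        c, _, rms = calibrate_planar(obs["left"], board, image_size=(1920, 1200))
        assert c.dist[0] == pytest.approx(-0.1, rel=0.05)
        assert rms < 1e-6

    def test_two_views_insufficient(self, board, noiseless_views):
        obs, _ = noiseless_views
        with pytest.raises(InsufficientViewsError):
            calibrate_planar(obs["left"][:2], board)

    def test_recovery_independent_of_pose_seed(self, board, rig):
        for seed in (5, 17):
            obs, _ = render_board_views(board, rig, n_views=10, seed=seed)
            c, _, _ = calibrate_planar(obs["left"], board,
                                       image_size=(1920, 1200))
            assert c.fx == pytest.approx(1200.0, rel=1e-3)


class TestRigExtrinsics:
    def test_noiseless_recovery_and_baseline(self, board, rig, noiseless_views):
        obs, _ = noiseless_views
        _, pl, _ = calibrate_planar(obs["left"], board, image_size=(1920, 1200))
        _, pr, _ = calibrate_planar(obs["right"], board, image_size=(1920, 1200))
        T, spread = estimate_rig_extrinsics(pl, pr)
        assert np.abs(T.translation - rig.T_right_from_left.translation).max() < 1e-9
        angle = np.linalg.norm(Rotation.from_matrix(T.rotation).as_rotvec())
        assert angle < 1e-9
        assert np.linalg.norm(T.translation) == pytest.approx(1.7, abs=1e-6)
        assert spread["n_views"] == 10

    def test_noisy_corner_translation_within_5mm(self, board, rig):
        """Pose-only Monte-Carlo: 0.5 px corner noise, 10 near-range views.

        Board-pose rotation errors couple with the board distance into the
        relative translation, so millimeter-level extrinsics require the
        near end of the tower's working range (3-5 m).
        """
        from fieldpheno.camera_geometry import estimate_board_pose

        obs, _ = render_board_views(board, rig, n_views=10,
                                    noise_sigma_px=0.5, seed=21,
                                    distance_range=(3.0, 5.0))
        pl = [estimate_board_pose(v, board, rig.left) for v in obs["left"]]
        pr = [estimate_board_pose(v, board, rig.right) for v in obs["right"]]
        T, _ = estimate_rig_extrinsics(pl, pr)
        err = np.linalg.norm(T.translation - rig.T_right_from_left.translation)
        assert err < 0.005

    def test_noisy_full_recalibration_translation_sanity(self, board, rig):
        # re-estimating intrinsics from the same noisy corners adds a
        # correlated depth-scale error; the bound is accordingly looser
        obs, _ = render_board_views(board, rig, n_views=10,
                                    noise_sigma_px=0.5, seed=21)
        _, pl, _ = calibrate_planar(obs["left"], board, image_size=(1920, 1200))
        _, pr, _ = calibrate_planar(obs["right"], board, image_size=(1920, 1200))
        T, _ = estimate_rig_extrinsics(pl, pr)
        err = np.linalg.norm(T.translation - rig.T_right_from_left.translation)
        assert err < 0.05


class TestReprojectionReport:
    def test_identical_lists_zero(self):
        px = np.arange(10, dtype=float).reshape(5, 2)
        rep = reprojection_error_report(px, px)
        assert rep.rms == 0 and rep.bias_u == 0 and rep.bias_v == 0

    def test_constant_vertical_offset(self):
        px = np.arange(10, dtype=float).reshape(5, 2)
        rep = reprojection_error_report(px, px + [0.0, 2.0])
        assert rep.rms == pytest.approx(2.0)
        assert rep.bias_v == pytest.approx(2.0)
        assert rep.bias_u == pytest.approx(0.0)

    def test_symmetric_pair(self):
        rep = reprojection_error_report(np.zeros((2, 2)),
                                        np.array([[1.0, 0.0], [-1.0, 0.0]]))
        assert rep.rms == pytest.approx(1.0)
        assert rep.bias_u == pytest.approx(0.0)

    def test_matches_brute_force_recomputation(self, rng):
        pred = rng.normal(size=(40, 2))
        obs = pred + rng.normal(size=(40, 2))
        rep = reprojection_error_report(pred, obs)
        sq = [
            (o[0] - p[0]) ** 2 + (o[1] - p[1]) ** 2
            for p, o in zip(pred, obs)
        ]
        assert rep.rms == pytest.approx(np.sqrt(sum(sq) / len(sq)))
        assert rep.bias_u == pytest.approx(np.mean(obs[:, 0] - pred[:, 0]))
        assert rep.bias_v == pytest.approx(np.mean(obs[:, 1] - pred[:, 1]))

    def test_empty_input_rejected(self):
        with pytest.raises(NoCorrespondencesError):
            reprojection_error_report(np.empty((0, 2)), np.empty((0, 2)))


rotvecs = st.lists(
    st.floats(-3.0, 3.0, allow_nan=False), min_size=3, max_size=3
)


class TestRigidTransform:
    @given(rotvecs, rotvecs, rotvecs)
    @settings(max_examples=50, deadline=None)
    def test_composition_stays_orthonormal(self, a, b, c):
        t = RigidTransform.from_rotvec(a, [0.1, 0, 0])
        for v in (b, c):
            t = t @ RigidTransform.from_rotvec(v, [0, 0.2, -0.1])
        err = np.abs(t.rotation.T @ t.rotation - np.eye(3)).max()
        assert err < 1e-9
        assert abs(np.linalg.det(t.rotation) - 1.0) < 1e-9

    def test_inverse_roundtrip(self, rng):
        t = RigidTransform.from_rotvec(rng.normal(size=3), rng.normal(size=3))
        pts = rng.normal(size=(20, 3))
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-12)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(InvalidParameterError):
            RigidTransform(np.eye(3) * 1.001, np.zeros(3))
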
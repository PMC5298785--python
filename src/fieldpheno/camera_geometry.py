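"""Pinhole camera model, planar-target calibration and stereo triangulation.

The three-camera rig (left RGB, right RGB, centered thermal) is modelled with
standard pinhole intrinsics plus the 5-coefficient radial-tangential lens
distortion (k1, k2, p1, p2, k3).  Calibration follows the classical
planar-target scheme: per-view homographies give a closed-form initial
estimate of the intrinsics, after which a damped least-squares refinement
minimises reprojection error jointly over intrinsics, distortion and
per-view board poses.  All extrinsics are stored relative to the left
(reference) camera.

Conventions
-----------
* Camera frame: right-handed, +z forward, +x right, +y down.
* Pixels: (0, 0) at the top-left corner, pixel centers on integer
  coordinates, u along +x, v along +y.
* ``T_a_from_b`` maps b-frame coordinates into the a-frame:
  ``x_a = R @ x_b + t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .errors import (
    BehindCameraError,
    DegenerateGeometryError,
    InsufficientViewsError,
    InvalidParameterError,
    InversionError,
    NoCorrespondencesError,
    NoOverlapError,
)

__all__ = [
    "CameraIntrinsics",
    "RigidTransform",
    "StereoThermalRig",
    "BoardModel",
    "ReprojectionReport",
    "project_point",
    "project_points",
    "undistort_pixel",
    "undistort_pixels",
    "triangulate_pair",
    "calibrate_planar",
    "estimate_board_pose",
    "estimate_rig_extrinsics",
    "reprojection_error_report",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CameraIntrinsics:
    """Pinhole matrix plus radial-tangential distortion for one camera.

    Parameters
    ----------
    fx, fy : float
        Focal lengths in pixels.
    cx, cy : float
        Principal point in pixels.
    skew : float
        Skew term of the pinhole matrix, pixels (0 for square pixels).
    dist : array-like of 5 floats
        Distortion coefficients ``(k1, k2, p1, p2, k3)``.
    image_size : (int, int)
        Sensor size ``(width, height)`` in pixels.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    skew: float = 0.0
    dist: np.ndarray = field(default_factory=lambda: np.zeros(5))
    image_size: tuple[int, int] = (1920, 1200)

    def __post_init__(self) -> None:
        self.dist = np.asarray(self.dist, dtype=float)
        if self.dist.shape != (5,):
            raise InvalidParameterError("dist must hold (k1, k2, p1, p2, k3)")
        if not np.all(np.isfinite(self.dist)):
            raise InvalidParameterError("distortion coefficients must be finite")
        if self.fx <= 0 or self.fy <= 0:
            raise InvalidParameterError("focal lengths must be positive")
        w, h = self.image_size
        if not (0 <= self.cx < w and 0 <= self.cy < h):
            raise InvalidParameterError("principal point must lie inside the image")

    @property
    def K(self) -> np.ndarray:
        """3x3 pinhole matrix."""
        return np.array(
            [
                [self.fx, self.skew, self.cx],
                [0.0, self.fy, self.cy],
                [0.0, 0.0, 1.0],
            ]
        )

    def contains(self, pixels: np.ndarray) -> np.ndarray:
        """Boolean mask of pixels whose coordinates fall inside the sensor."""
        p = np.atleast_2d(np.asarray(pixels, dtype=float))
        w, h = self.image_size
        return (
            (p[:, 0] >= 0) & (p[:, 0] <= w - 1) & (p[:, 1] >= 0) & (p[:, 1] <= h - 1)
        )


_ORTHO_TOL = 1e-9


@dataclass
class RigidTransform:
    """Rotation + translation; ``apply`` maps source-frame points to target."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.rotation.shape != (3, 3):
            raise InvalidParameterError("rotation must be 3x3")
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > _ORTHO_TOL:
            raise InvalidParameterError(f"rotation not orthonormal (err={err:.2e})")
        if abs(np.linalg.det(self.rotation) - 1.0) > _ORTHO_TOL:
            raise InvalidParameterError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        return cls(Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(),
                   translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first, then ``self``)."""
        # re-orthonormalise so long chains never drift past the invariant
        r = Rotation.from_matrix(self.rotation @ other.rotation).as_matrix()
        return RigidTransform(r, self.rotation @ other.translation + self.translation)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)


@dataclass
class StereoThermalRig:
    """Calibrated three-camera rig; the left RGB camera is the reference.

    The thermal camera sits between the two RGB cameras, so its translation
    magnitude must be smaller than the stereo baseline.
    """

    left: CameraIntrinsics
    right: CameraIntrinsics
    thermal: CameraIntrinsics
    T_right_from_left: RigidTransform
    T_thermal_from_left: RigidTransform

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise InvalidParameterError("stereo baseline must be positive")
        t_th = np.linalg.norm(self.T_thermal_from_left.translation)
        if t_th >= self.baseline:
            raise InvalidParameterError(
                "thermal camera must lie between the RGB pair "
                f"(|t_thermal|={t_th:.3f} >= baseline={self.baseline:.3f})"
            )

    @property
    def baseline(self) -> float:
        """Distance between the RGB optical centers, meters."""
        return float(np.linalg.norm(self.T_right_from_left.translation))


@dataclass
class BoardModel:
    """Planar calibration target: a grid of isolated squares on the z=0 plane.

    ``corner_coordinates`` holds the 3D position of every identified corner in
    the board frame; corner ids are row indices into this array and remain
    stable across views and cameras.
    """

    square_size: float
    pitch: float
    layout: tuple[int, int]
    corner_coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.corner_coordinates = np.asarray(self.corner_coordinates, dtype=float)
        if self.square_size <= 0 or self.pitch <= 0:
            raise InvalidParameterError("square_size and pitch must be positive")
        if self.corner_coordinates.ndim != 2 or self.corner_coordinates.shape[1] != 3:
            raise InvalidParameterError("corner_coordinates must be (n, 3)")
        if np.abs(self.corner_coordinates[:, 2]).max(initial=0.0) > 0:
            raise InvalidParameterError("board corners must lie on z = 0")

    @property
    def n_corners(self) -> int:
        return len(self.corner_coordinates)


@dataclass
class ReprojectionReport:
    """RMS + per-axis bias summary of paired pixel residuals.

    ``residuals`` are (observed - predicted); ``bias_u``/``bias_v`` are their
    mean signed components, the diagnostic that exposes systematic shifts
    such as a vertical registration bias.
    """

    rms: float
    bias_u: float
    bias_v: float
    residuals: np.ndarray
    n_points: int

    def as_dict(self) -> dict:
        return {
            "rms": self.rms,
            "bias_u": self.bias_u,
            "bias_v": self.bias_v,
            "n_points": self.n_points,
        }


# ---------------------------------------------------------------------------
# projection model
# ---------------------------------------------------------------------------

def _distort_normalized(xy: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Apply the radial-tangential model to normalized coordinates (n, 2)."""
    k1, k2, p1, p2, k3 = dist
    x, y = xy[:, 0], xy[:, 1]
    r2 = x * x + y * y
    radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
    xd = x * radial + 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
    yd = y * radial + p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
    return np.column_stack([xd, yd])


def project_points(points: np.ndarray, cam: CameraIntrinsics) -> np.ndarray:
    """Project (n, 3) camera-frame points to (n, 2) pixels.

    Raises
    ------
    BehindCameraError
        If any point has z <= 0.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    z = pts[:, 2]
    if np.any(z <= 0):
        raise BehindCameraError("point(s) with z <= 0 cannot be projected")
    xy = pts[:, :2] / z[:, None]
    xd = _distort_normalized(xy, cam.dist)
    u = cam.fx * xd[:, 0] + cam.skew * xd[:, 1] + cam.cx
    v = cam.fy * xd[:, 1] + cam.cy
    return np.column_stack([u, v])


def project_point(point: np.ndarray, cam: CameraIntrinsics) -> np.ndarray:
    """Project a single camera-frame 3D point to a pixel (u, v)."""
    return project_points(np.asarray(point, float).reshape(1, 3), cam)[0]


def undistort_pixels(
    pixels: np.ndarray,
    cam: CameraIntrinsics,
    max_iter: int = 50,
    tol: float = 1e-12,
) -> np.ndarray:
    """Map (n, 2) pixels to undistorted normalized image coordinates.

    Fixed-point inversion of the distortion polynomial; converges quadratically
    fast in practice for normalized radii up to ~0.7.

    Raises
    ------
    InversionError
        If the iteration does not converge within ``max_iter``.
    """
    px = np.atleast_2d(np.asarray(pixels, dtype=float))
    yd = (px[:, 1] - cam.cy) / cam.fy
    xd = (px[:, 0] - cam.cx - cam.skew * yd) / cam.fx
    target = np.column_stack([xd, yd])
    if not np.any(cam.dist):
        return target
    xy = target.copy()
    k1, k2, p1, p2, k3 = cam.dist
    for _ in range(max_iter):
        x, y = xy[:, 0], xy[:, 1]
        r2 = x * x + y * y
        radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
        dx = 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
        dy = p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
        new = (target - np.column_stack([dx, dy])) / radial[:, None]
        step = np.abs(new - xy).max()
        xy = new
        if step < tol:
            break
    else:
        raise InversionError(
            f"distortion inversion did not converge in {max_iter} iterations"
        )
    # verify by forward mapping
    if np.abs(_distort_normalized(xy, cam.dist) - target).max() > 1e-8:
        raise InversionError("distortion inversion failed the forward check")
    return xy


def undistort_pixel(pixel: np.ndarray, cam: CameraIntrinsics, **kw) -> np.ndarray:
    """Undistort a single pixel to normalized image coordinates (x, y)."""
    return undistort_pixels(np.asarray(pixel, float).reshape(1, 2), cam, **kw)[0]


# ---------------------------------------------------------------------------
# triangulation
# ---------------------------------------------------------------------------

def triangulate_pair(
    pixel_left: np.ndarray,
    pixel_right: np.ndarray,
    rig: StereoThermalRig,
    min_angle_rad: float = 1e-8,
) -> np.ndarray:
    """Triangulate one left/right pixel pair to a 3D point in the left frame.

    Uses the midpoint of the common perpendicular of the two viewing rays,
    which coincides with the linear least-squares point for two rays.

    Raises
    ------
    DegenerateGeometryError
        If the rays are parallel within ``min_angle_rad``.
    """
    nl = undistort_pixel(pixel_left, rig.left)
    nr = undistort_pixel(pixel_right, rig.right)
    d1 = np.array([nl[0], nl[1], 1.0])
    d1 /= np.linalg.norm(d1)
    T_lr = rig.T_right_from_left.inverse()
    d2 = T_lr.rotation @ np.array([nr[0], nr[1], 1.0])
    d2 /= np.linalg.norm(d2)
    o1 = np.zeros(3)
    o2 = T_lr.translation  # right camera center in the left frame

    cross = np.cross(d1, d2)
    sin_angle = np.linalg.norm(cross)
    if sin_angle < min_angle_rad:
        raise DegenerateGeometryError(
            f"viewing rays nearly parallel (sin angle = {sin_angle:.2e})"
        )
    # closest points: o1 + s d1 and o2 + t d2
    b = o2 - o1
    d12 = d1 @ d2
    denom = 1.0 - d12 * d12
    s = (b @ d1 - (b @ d2) * d12) / denom
    t = ((b @ d1) * d12 - b @ d2) / denom
    return 0.5 * ((o1 + s * d1) + (o2 + t * d2))


def triangulate_pairs(
    pixels_left: np.ndarray, pixels_right: np.ndarray, rig: StereoThermalRig
) -> np.ndarray:
    """Vectorized wrapper over :func:`triangulate_pair` for (n, 2) arrays."""
    pl = np.atleast_2d(pixels_left)
    pr = np.atleast_2d(pixels_right)
    return np.array([triangulate_pair(a, b, rig) for a, b in zip(pl, pr)])


# ---------------------------------------------------------------------------
# planar calibration
# ---------------------------------------------------------------------------

def _normalize_2d(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Similarity-normalize 2D points (mean 0, mean distance sqrt(2))."""
    mean = pts.mean(axis=0)
    scale = np.sqrt(2.0) / max(np.mean(np.linalg.norm(pts - mean, axis=1)), 1e-12)
    T = np.array(
        [[scale, 0, -scale * mean[0]], [0, scale, -scale * mean[1]], [0, 0, 1]]
    )
    h = np.column_stack([pts, np.ones(len(pts))]) @ T.T
    return h[:, :2], T


def _homography(board_xy: np.ndarray, pixels: np.ndarray) -> np.ndarray:
    """Normalized DLT homography mapping board (X, Y) to pixels."""
    if len(board_xy) < 4:
        raise DegenerateGeometryError("need at least 4 corners for a homography")
    src, Ts = _normalize_2d(board_xy)
    dst, Td = _normalize_2d(pixels)
    n = len(src)
    A = np.zeros((2 * n, 9))
    A[0::2, 0:2] = src
    A[0::2, 2] = 1.0
    A[0::2, 6:8] = -dst[:, 0:1] * src
    A[0::2, 8] = -dst[:, 0]
    A[1::2, 3:5] = src
    A[1::2, 5] = 1.0
    A[1::2, 6:8] = -dst[:, 1:2] * src
    A[1::2, 8] = -dst[:, 1]
    _, s, vt = np.linalg.svd(A)
    if s[-2] < 1e-9 * s[0]:
        raise DegenerateGeometryError("rank-deficient homography system")
    H = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ H @ Ts
    return H / H[2, 2]


def _vij(H: np.ndarray, i: int, j: int) -> np.ndarray:
    """Constraint row of the absolute-conic system for columns i, j of H."""
    return np.array(
        [
            H[0, i] * H[0, j],
            H[0, i] * H[1, j] + H[1, i] * H[0, j],
            H[1, i] * H[1, j],
            H[2, i] * H[0, j] + H[0, i] * H[2, j],
            H[2, i] * H[1, j] + H[1, i] * H[2, j],
            H[2, i] * H[2, j],
        ]
    )


def _intrinsics_from_homographies(
    Hs: Sequence[np.ndarray], image_size: tuple[int, int]
) -> np.ndarray:
    """Closed-form intrinsics (fx, fy, cx, cy, skew) from >= 3 homographies."""
    V = []
    for H in Hs:
        V.append(_vij(H, 0, 1))
        V.append(_vij(H, 0, 0) - _vij(H, 1, 1))
    V = np.asarray(V)
    _, _, vt = np.linalg.svd(V)
    B11, B12, B22, B13, B23, B33 = vt[-1]
    denom = B11 * B22 - B12 * B12
    if abs(denom) < 1e-30:
        raise DegenerateGeometryError("degenerate configuration: coplanar poses")
    cy = (B12 * B13 - B11 * B23) / denom
    lam = B33 - (B13 * B13 + cy * (B12 * B13 - B11 * B23)) / B11
    if lam / B11 <= 0:
        raise DegenerateGeometryError("degenerate configuration (negative focal)")
    fx = np.sqrt(lam / B11)
    fy = np.sqrt(lam * B11 / denom)
    skew = -B12 * fx * fx * fy / lam
    cx = skew * cy / fx - B13 * fx * fx / lam
    return np.array([fx, fy, cx, cy, skew])


def _pose_from_homography(H: np.ndarray, Kmat: np.ndarray) -> RigidTransform:
    """Initial board-to-camera pose from a homography and intrinsics."""
    Kinv = np.linalg.inv(Kmat)
    h1, h2, h3 = H[:, 0], H[:, 1], H[:, 2]
    lam = 1.0 / np.linalg.norm(Kinv @ h1)
    r1 = lam * (Kinv @ h1)
    r2 = lam * (Kinv @ h2)
    t = lam * (Kinv @ h3)
    r3 = np.cross(r1, r2)
    R = np.column_stack([r1, r2, r3])
    # nearest rotation via SVD
    U, _, Vt = np.linalg.svd(R)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = -R
        t = -t
    if t[2] < 0:  # board must be in front of the camera
        R = R @ np.diag([-1.0, -1.0, 1.0])
        t = -t
    return RigidTransform(R, t)


def calibrate_planar(
    observations: Sequence[Mapping[int, tuple[float, float]]],
    board: BoardModel,
    image_size: tuple[int, int] = (1920, 1200),
    fix_skew: bool = True,
    max_iter: int = 200,
) -> tuple[CameraIntrinsics, list[RigidTransform], float]:
    """Calibrate one camera from corner observations of the planar target.

    Parameters
    ----------
    observations : sequence of {corner_id: (u, v)}
        One mapping per view; corner ids index ``board.corner_coordinates``.
    board : BoardModel
        The calibration target geometry.
    image_size : (int, int)
        Sensor size recorded in the returned intrinsics.
    fix_skew : bool
        Hold the skew term at zero during refinement (square pixels).
    max_iter : int
        Cap on damped least-squares iterations.

    Returns
    -------
    (CameraIntrinsics, list of per-view board-to-camera RigidTransform, rms)
        ``rms`` is the final reprojection RMS in pixels.

    Raises
    ------
    InsufficientViewsError
        Fewer than 3 views with >= 4 corners each.
    DegenerateGeometryError
        Rank-deficient homography or conic system.
    """
    usable = [v for v in observations if len(v) >= 4]
    if len(usable) < 3:
        raise InsufficientViewsError(
            f"need >= 3 views with >= 4 corners, got {len(usable)}"
        )

    board_pts = board.corner_coordinates
    views = []
    for obs in usable:
        ids = np.array(sorted(obs.keys()), dtype=int)
        px = np.array([obs[i] for i in ids], dtype=float)
        views.append((ids, px))

    Hs = [_homography(board_pts[ids][:, :2], px) for ids, px in views]
    fx, fy, cx, cy, skew = _intrinsics_from_homographies(Hs, image_size)
    if fix_skew:
        skew = 0.0
    K0 = np.array([[fx, skew, cx], [0, fy, cy], [0, 0, 1.0]])
    poses0 = [_pose_from_homography(H, K0) for H in Hs]

    n_views = len(views)

    def unpack(p):
        fx, fy, cx, cy = p[0:4]
        skew = 0.0 if fix_skew else p[4]
        dist = p[5:10]
        cam = CameraIntrinsics.__new__(CameraIntrinsics)
        cam.fx, cam.fy, cam.cx, cam.cy, cam.skew = fx, fy, cx, cy, skew
        cam.dist = dist
        cam.image_size = image_size
        poses = []
        for i in range(n_views):
            q = p[10 + 6 * i : 16 + 6 * i]
            poses.append((Rotation.from_rotvec(q[:3]).as_matrix(), q[3:6]))
        return cam, poses

    def residuals(p):
        cam, poses = unpack(p)
        res = []
        for (ids, px), (R, t) in zip(views, poses):
            pc = board_pts[ids] @ R.T + t
            res.append((project_points(pc, cam) - px).ravel())
        return np.concatenate(res)

    p0 = np.zeros(10 + 6 * n_views)
    p0[0:4] = fx, fy, cx, cy
    p0[4] = skew
    for i, pose in enumerate(poses0):
        p0[10 + 6 * i : 13 + 6 * i] = Rotation.from_matrix(pose.rotation).as_rotvec()
        p0[13 + 6 * i : 16 + 6 * i] = pose.translation

    sol = least_squares(
        residuals,
        p0,
        method="lm",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=max_iter * len(p0),
    )
    cam_fit, poses_fit = unpack(sol.x)
    cam = CameraIntrinsics(
        fx=cam_fit.fx,
        fy=cam_fit.fy,
        cx=cam_fit.cx,
        cy=cam_fit.cy,
        skew=cam_fit.skew,
        dist=cam_fit.dist,
        image_size=image_size,
    )
    poses = [RigidTransform(Rotation.from_matrix(R).as_matrix(), t)
             for R, t in poses_fit]
    rms = float(np.sqrt(np.mean(np.sum(sol.fun.reshape(-1, 2) ** 2, axis=1))))
    return cam, poses, rms


def estimate_board_pose(
    observation: Mapping[int, tuple[float, float]],
    board: BoardModel,
    cam: CameraIntrinsics,
) -> RigidTransform:
    """Board-to-camera pose from one view with known intrinsics (planar PnP).

    Homography-based initialization refined by damped least squares on the
    reprojection error, holding the intrinsics fixed.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 4 corners or a rank-deficient homography.
    """
    ids = np.array(sorted(observation.keys()), dtype=int)
    px = np.array([observation[i] for i in ids], dtype=float)
    pts = board.corner_coordinates[ids]
    und = undistort_pixels(px, cam)
    H = _homography(pts[:, :2], und)
    pose0 = _pose_from_homography(H, np.eye(3))

    def residuals(p):
        R = Rotation.from_rotvec(p[:3]).as_matrix()
        pc = pts @ R.T + p[3:6]
        return (project_points(pc, cam) - px).ravel()

    p0 = np.concatenate(
        [Rotation.from_matrix(pose0.rotation).as_rotvec(), pose0.translation]
    )
    sol = least_squares(residuals, p0, method="lm", xtol=1e-15, ftol=1e-15,
                        gtol=1e-15)
    return RigidTransform(
        Rotation.from_rotvec(sol.x[:3]).as_matrix(), sol.x[3:6]
    )


# ---------------------------------------------------------------------------
# rig extrinsics
# ---------------------------------------------------------------------------

def estimate_rig_extrinsics(
    poses_ref: Sequence[RigidTransform],
    poses_other: Sequence[RigidTransform],
    view_ids_ref: Sequence[int] | None = None,
    view_ids_other: Sequence[int] | None = None,
) -> tuple[RigidTransform, dict]:
    """Combine per-view board poses of two cameras into one relative transform.

    Each pose is the board-to-camera transform of one shared view.  The
    per-view relative transform ``T_other_from_ref = pose_other ∘ pose_ref⁻¹``
    is averaged over views: rotations by the quaternion mean, translations by
    the arithmetic mean.

    Returns
    -------
    (RigidTransform, dict)
        The averaged transform and a spread report with per-view rotation
        angle deviations (rad) and translation deviations (m).

    Raises
    ------
    NoOverlapError
        If the cameras share no views.
    """
    if view_ids_ref is None:
        view_ids_ref = list(range(len(poses_ref)))
    if view_ids_other is None:
        view_ids_other = list(range(len(poses_other)))
    by_ref = dict(zip(view_ids_ref, poses_ref))
    by_other = dict(zip(view_ids_other, poses_other))
    shared = sorted(set(by_ref) & set(by_other))
    if not shared:
        raise NoOverlapError("no shared views between the two cameras")

    rels = [by_other[i] @ by_ref[i].inverse() for i in shared]
    rot_mean = Rotation.mean(
        Rotation.from_matrix(np.stack([r.rotation for r in rels]))
    ).as_matrix()
    t_mean = np.mean([r.translation for r in rels], axis=0)
    combined = RigidTransform(rot_mean, t_mean)

    rot_dev = [
        float(
            np.linalg.norm(
                (Rotation.from_matrix(r.rotation)
                 * Rotation.from_matrix(rot_mean).inv()).as_rotvec()
            )
        )
        for r in rels
    ]
    t_dev = [float(np.linalg.norm(r.translation - t_mean)) for r in rels]
    spread = {
        "n_views": len(shared),
        "rotation_dev_rad": rot_dev,
        "translation_dev_m": t_dev,
    }
    return combined, spread


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def reprojection_error_report(
    predicted: np.ndarray, observed: np.ndarray
) -> ReprojectionReport:
    """Summarize paired pixel residuals as RMS plus per-axis signed bias.

    ``rms = sqrt(mean ||observed - predicted||²)`` over point pairs;
    ``bias_u``/``bias_v`` are mean signed residual components.

    Raises
    ------
    NoCorrespondencesError
        On empty input.
    """
    pred = np.atleast_2d(np.asarray(predicted, dtype=float))
    obs = np.atleast_2d(np.asarray(observed, dtype=float))
    if pred.size == 0 or obs.size == 0:
        raise NoCorrespondencesError("no correspondences to report on")
    if pred.shape != obs.shape:
        raise InvalidParameterError("predicted/observed must be equal-length pairs")
    res = obs - pred
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    bias = res.mean(axis=0)
    return ReprojectionReport(
        rms=rms,
        bias_u=float(bias[0]),
        bias_v=float(bias[1]),
        residuals=res,
        n_points=len(res),
    )
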
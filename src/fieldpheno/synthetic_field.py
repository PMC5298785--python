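"""Seed-controlled synthetic crop-field scenes with exact analytic ground truth.

Everything the pipeline consumes — calibration-board corner observations,
plant/plot point clouds, thermal rasters, and environmental sensor logs — can
be generated here with known parameters, so each estimator can be validated
against exact ground truth without any field data.

The generator emulates the field conditions the rig was built for:

* a 1.5 m × 1.5 m calibration board carrying 81 isolated black 8 × 8 cm
  squares (324 identified corners), imaged from 10 poses at 3–10 m;
* a camera tower with a ~1.7 m RGB stereo baseline and a thermal camera
  centered between the RGB pair;
* maize-like rows at 76/114/152 cm spacing, 10 plants per sampled plot,
  with known collar heights and closed-form single-sided leaf areas;
* a weed layer whose height distribution (< 0.3 m) is distinctly below the
  crop canopy (collar heights ≥ 0.5 m);
* leaf and soil temperature fields for the thermal camera.

Leaves are developable ribbon strips with a parabolic droop: the strip is a
centerline swept along a constant horizontal ruling, so its single-sided
area is exactly ``arc_length × width`` — the analytic LAI ground truth —
while the sampled mesh converges to that value with tessellation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .camera_geometry import (
    BoardModel,
    CameraIntrinsics,
    RigidTransform,
    StereoThermalRig,
    project_points,
)
from .canopy_traits import LABEL_CROP, LABEL_SOIL, LABEL_WEED, PlantPointCloud
from .env_sensors import LUX_TO_PPFD, SensorSeries
from .errors import EmptyInputError, InvalidParameterError
from .thermal_fusion import ThermalRaster

__all__ = [
    "SceneGroundTruth",
    "default_rig",
    "make_board",
    "render_board_views",
    "make_plant",
    "make_plot_scene",
    "render_thermal",
    "simulate_sensor_logs",
    "look_down_pose",
]

#: supported row spacings, meters (30/45/60 inch rows)
ROW_SPACINGS = (0.76, 1.14, 1.52)


# ---------------------------------------------------------------------------
# rig and board
# ---------------------------------------------------------------------------

def default_rig(
    baseline: float = 1.7,
    rgb_focal_px: float = 1200.0,
    rgb_size: tuple[int, int] = (1920, 1200),
    thermal_focal_px: float = 600.0,
    thermal_size: tuple[int, int] = (640, 480),
    rgb_dist: Sequence[float] = (0, 0, 0, 0, 0),
    thermal_dist: Sequence[float] = (0, 0, 0, 0, 0),
) -> StereoThermalRig:
    """Synthetic tower rig: two RGB cameras 1.7 m apart, thermal centered.

    All three cameras share orientation; the right camera sits ``baseline``
    meters along +x of the left (reference) camera and the thermal camera at
    the midpoint.
    """
    left = CameraIntrinsics(rgb_focal_px, rgb_focal_px,
                            rgb_size[0] / 2, rgb_size[1] / 2,
                            dist=np.asarray(rgb_dist, float), image_size=rgb_size)
    right = CameraIntrinsics(rgb_focal_px, rgb_focal_px,
                             rgb_size[0] / 2, rgb_size[1] / 2,
                             dist=np.asarray(rgb_dist, float), image_size=rgb_size)
    thermal = CameraIntrinsics(thermal_focal_px, thermal_focal_px,
                               thermal_size[0] / 2, thermal_size[1] / 2,
                               dist=np.asarray(thermal_dist, float),
                               image_size=thermal_size)
    # cameras to the right sit at +x in the left frame; mapping left->right
    # coordinates subtracts the offset
    T_rl = RigidTransform(np.eye(3), [-baseline, 0.0, 0.0])
    T_tl = RigidTransform(np.eye(3), [-baseline / 2, 0.0, 0.0])
    return StereoThermalRig(left, right, thermal, T_rl, T_tl)


def make_board(
    n_squares_side: int = 9,
    square_size: float = 0.08,
    pitch: float = 0.16,
) -> BoardModel:
    """Calibration target: isolated black squares on a white board.

    Default geometry: 9 × 9 squares of 8 × 8 cm at 16 cm pitch, centered on
    the board origin — 81 squares, 324 identified corners, fitting inside a
    1.5 × 1.5 m board.  Corner ids are ``square_index * 4 + corner_index``
    with squares row-major from the top-left and corners counter-clockwise
    from each square's minimum-x/minimum-y vertex.
    """
    n = n_squares_side
    span = (n - 1) * pitch + square_size
    origin = -span / 2.0
    corners = []
    for row in range(n):
        for col in range(n):
            x0 = origin + col * pitch
            y0 = origin + row * pitch
            s = square_size
            corners.extend(
                [(x0, y0, 0.0), (x0 + s, y0, 0.0),
                 (x0 + s, y0 + s, 0.0), (x0, y0 + s, 0.0)]
            )
    return BoardModel(
        square_size=square_size,
        pitch=pitch,
        layout=(n, n),
        corner_coordinates=np.asarray(corners, dtype=float),
    )


def render_board_views(
    board: BoardModel,
    rig: StereoThermalRig,
    n_views: int = 10,
    noise_sigma_px: float = 0.0,
    seed: int = 0,
    distance_range: tuple[float, float] = (3.0, 10.0),
    max_tilt_deg: float = 45.0,
) -> tuple[dict[str, list[dict[int, tuple[float, float]]]], list[RigidTransform]]:
    """Render corner observations of the board in all three cameras.

    Board poses are sampled with the board center ``distance_range`` meters
    in front of the rig (aimed between the RGB pair so all cameras see it)
    and tilts up to ``max_tilt_deg`` about the in-plane axes.  Corners are
    projected through each camera's full distortion model, Gaussian pixel
    noise is added, and corners falling outside a camera's frame are dropped
    for that camera only.

    Returns
    -------
    (observations, poses)
        ``observations[camera][view]`` maps corner id → (u, v) for camera in
        ``{"left", "right", "thermal"}``; ``poses[view]`` is the true
        board-to-left-camera transform.
    """
    if n_views < 1:
        raise InvalidParameterError("n_views must be >= 1")
    if noise_sigma_px < 0:
        raise InvalidParameterError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    cams = {"left": rig.left, "right": rig.right, "thermal": rig.thermal}
    T_cam_from_left = {
        "left": RigidTransform.identity(),
        "right": rig.T_right_from_left,
        "thermal": rig.T_thermal_from_left,
    }
    obs: dict[str, list[dict[int, tuple[float, float]]]] = {k: [] for k in cams}
    poses: list[RigidTransform] = []
    mid = np.array([rig.baseline / 2.0, 0.0, 0.0])
    for _ in range(n_views):
        d = rng.uniform(*distance_range)
        # small lateral scatter, shrinking with proximity so the board stays
        # in all frames
        lateral = rng.uniform(-0.08, 0.08, size=2) * d
        center = mid + np.array([lateral[0], lateral[1], d])
        tilt = np.deg2rad(rng.uniform(-max_tilt_deg, max_tilt_deg, size=2))
        roll = rng.uniform(-np.pi, np.pi)
        Rz = _rot_z(roll)
        Rx = _rot_x(tilt[0])
        Ry = _rot_y(tilt[1])
        R = Rx @ Ry @ Rz
        pose = RigidTransform(R, center)
        poses.append(pose)
        pts_left = pose.apply(board.corner_coordinates)
        for name, cam in cams.items():
            pts = T_cam_from_left[name].apply(pts_left)
            px = project_points(pts, cam)
            if noise_sigma_px > 0:
                px = px + rng.normal(0.0, noise_sigma_px, size=px.shape)
            visible = cam.contains(px)
            obs[name].append(
                {int(i): (float(px[i, 0]), float(px[i, 1]))
                 for i in np.where(visible)[0]}
            )
    return obs, poses


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


# ---------------------------------------------------------------------------
# plants
# ---------------------------------------------------------------------------

def _parabola_arclength(r: float, a: float, beta: float) -> float:
    """Arc length of z = a·r − β·r² from 0 to r (closed form)."""
    if beta == 0:
        return r * np.sqrt(1.0 + a * a)

    def F(u: float) -> float:
        return 0.5 * (u * np.sqrt(1.0 + u * u) + np.arcsinh(u))

    return (F(a) - F(a - 2.0 * beta * r)) / (2.0 * beta)


def _radius_for_arclength(L: float, a: float, beta: float) -> float:
    """Radial extent giving centerline arc length L (inverts the closed form)."""
    hi = L
    while _parabola_arclength(hi, a, beta) < L:
        hi *= 2.0
    return brentq(lambda r: _parabola_arclength(r, a, beta) - L, 0.0, hi,
                  xtol=1e-14)


@dataclass
class RibbonLeaf:
    """One parametric leaf: attachment, direction, droop, and exact area."""

    attach: np.ndarray          # 3D attachment point on the stem
    azimuth: float              # outward direction, rad
    elevation: float            # initial tangent angle above horizontal, rad
    droop: float                # parabola coefficient beta (1/m)
    length: float               # centerline arc length, m
    width: float                # ribbon width, m

    @property
    def area(self) -> float:
        """Single-sided surface area, exactly arc_length × width."""
        return self.length * self.width

    def centerline(self, s: np.ndarray) -> np.ndarray:
        """Centerline points at arc-length parameters s ∈ [0, length]."""
        a = np.tan(self.elevation)
        r_max = _radius_for_arclength(self.length, a, self.droop)
        grid_r = np.linspace(0.0, r_max, 512)
        grid_s = np.array([_parabola_arclength(r, a, self.droop) for r in grid_r])
        r = np.interp(s, grid_s, grid_r)
        zeta = a * r - self.droop * r * r
        dir_xy = np.array([np.cos(self.azimuth), np.sin(self.azimuth), 0.0])
        return self.attach + r[:, None] * dir_xy + zeta[:, None] * np.array([0, 0, 1.0])

    @property
    def ruling(self) -> np.ndarray:
        """Constant horizontal ruling direction (perpendicular to the droop plane)."""
        return np.array([-np.sin(self.azimuth), np.cos(self.azimuth), 0.0])

    def mesh(self, n_segments: int = 24) -> np.ndarray:
        """Triangulated strip, shape (2·n_segments, 3, 3)."""
        s = np.linspace(0.0, self.length, n_segments + 1)
        c = self.centerline(s)
        h = self.ruling * (self.width / 2.0)
        lo, hi = c - h, c + h
        tris = []
        for i in range(n_segments):
            tris.append([lo[i], hi[i], hi[i + 1]])
            tris.append([lo[i], hi[i + 1], lo[i + 1]])
        return np.asarray(tris)

    def sample_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n points uniform over the (developable) strip surface."""
        s = rng.uniform(0.0, self.length, n)
        w = rng.uniform(-self.width / 2.0, self.width / 2.0, n)
        return self.centerline(s) + w[:, None] * self.ruling


@dataclass
class PlantGroundTruth:
    """Exact per-plant quantities the estimators are validated against."""

    collar_height: float
    leaf_areas: list[float]
    leaves: list[RibbonLeaf]
    position: np.ndarray

    @property
    def total_leaf_area(self) -> float:
        return float(sum(self.leaf_areas))


def make_plant(
    collar_height: float = 1.0,
    n_leaves: int = 10,
    leaf_length: float = 0.6,
    leaf_width: float = 0.08,
    points_per_m2: float = 4000.0,
    seed: int = 0,
    position: Sequence[float] = (0.0, 0.0),
    stem_radius: float = 0.006,
    flat_leaves: bool = False,
) -> tuple[PlantPointCloud, PlantGroundTruth]:
    """One maize-like plant: vertical stem plus drooping ribbon leaves.

    The topmost leaf attaches exactly at ``collar_height`` (the height
    reference used by the manual protocol).  Leaf centerline arc length is
    ``leaf_length``, so each single-sided leaf area is exactly
    ``leaf_length × leaf_width``.  ``flat_leaves`` suppresses droop
    (horizontal rectangles) for closed-form sanity checks.

    Returns the sampled green-labeled point cloud and the ground truth.
    """
    if collar_height <= 0 or leaf_length <= 0 or leaf_width <= 0 \
            or points_per_m2 <= 0 or stem_radius <= 0 or n_leaves < 0:
        raise InvalidParameterError("invalid plant parameters")
    rng = np.random.default_rng(seed)
    pos = np.asarray([position[0], position[1], 0.0], dtype=float)

    # stem point sample (cylinder surface)
    stem_area = 2 * np.pi * stem_radius * collar_height
    n_stem = max(int(stem_area * points_per_m2), 40)
    theta = rng.uniform(0, 2 * np.pi, n_stem)
    z = rng.uniform(0, collar_height, n_stem)
    stem_pts = pos + np.column_stack(
        [stem_radius * np.cos(theta), stem_radius * np.sin(theta), z]
    )

    leaves: list[RibbonLeaf] = []
    leaf_pts = []
    if n_leaves > 0:
        # attachment heights from ~30% of the stem up to the collar, the
        # topmost exactly at collar_height; low attachments stay above the
        # weed band so the canopy keeps its distinct height distribution
        lo = max(0.3 * collar_height, min(0.3, 0.6 * collar_height))
        if n_leaves == 1:
            attach_z = np.array([collar_height])
        else:
            attach_z = np.linspace(lo, collar_height, n_leaves)
        attach_z[-1] = collar_height
        for i, az_z in enumerate(attach_z):
            azimuth = rng.uniform(0, 2 * np.pi)
            if flat_leaves:
                elevation, droop = 0.0, 0.0
            else:
                # leaves arch downward from the collar: shallow initial
                # elevation, droop capped so tips stay clear of the soil
                # (low-leaf tips hold above ~0.25 m, as in a maize canopy)
                elevation = np.deg2rad(rng.uniform(0.0, 15.0))
                droop_cap = max((az_z - 0.25) / leaf_length**2, 0.05)
                droop = min(rng.uniform(0.5, 1.5), droop_cap)
            leaf = RibbonLeaf(
                attach=pos + np.array([0.0, 0.0, az_z]),
                azimuth=azimuth,
                elevation=elevation,
                droop=droop,
                length=leaf_length,
                width=leaf_width,
            )
            leaves.append(leaf)
            n_pts = max(int(leaf.area * points_per_m2), 20)
            leaf_pts.append(leaf.sample_points(n_pts, rng))

    pts = np.vstack([stem_pts] + leaf_pts) if leaf_pts else stem_pts
    n = len(pts)
    # green canopy colors with mild variation
    g = rng.integers(120, 180, n)
    colors = np.column_stack([g // 3, g, g // 3]).astype(np.uint8)
    labels = np.full(n, LABEL_CROP, dtype=np.uint8)
    cloud = PlantPointCloud(pts, colors, labels=labels)
    gt = PlantGroundTruth(
        collar_height=collar_height,
        leaf_areas=[lf.area for lf in leaves],
        leaves=leaves,
        position=pos[:2],
    )
    return cloud, gt


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

@dataclass
class SceneGroundTruth:
    """Exact ground truth for one generated plot scene."""

    collar_heights: np.ndarray
    leaf_areas: list[list[float]]
    plant_positions: np.ndarray
    row_spacing: float
    roi: tuple[float, float, float, float]
    plant_index: np.ndarray          # per-point plant id (-1 for soil/weed)
    labels: np.ndarray
    leaf_temp: float | None = None
    soil_temp: float | None = None
    plants: list[PlantGroundTruth] = field(default_factory=list)

    @property
    def roi_area(self) -> float:
        x0, y0, x1, y1 = self.roi
        return (x1 - x0) * (y1 - y0)

    @property
    def lai_leafsum(self) -> float:
        """Analytic LAI = Σ leaf areas / ROI area."""
        return float(sum(sum(a) for a in self.leaf_areas) / self.roi_area)


def make_plot_scene(
    n_plants: int = 10,
    row_spacing: float = 0.76,
    weed_fraction: float = 0.1,
    soil_color: tuple[int, int, int] = (120, 84, 50),
    seed: int = 0,
    in_row_spacing: float = 0.23,
    collar_height_mean: float = 1.0,
    collar_height_sd: float = 0.05,
    n_leaves: int = 10,
    leaf_length: float = 0.6,
    leaf_width: float = 0.08,
    points_per_m2: float = 4000.0,
    soil_points_per_m2: float = 4000.0,
) -> tuple[PlantPointCloud, SceneGroundTruth]:
    """A sampled plot: a row of plants over soil, with an optional weed layer.

    Plants sit along the x axis at ``in_row_spacing`` (10 plants per sampled
    plot by default); the plot ROI is the row-spacing × row-length rectangle
    centered on the row.  Weed tufts are short green point clusters capped at
    0.3 m, well separated from the crop canopy (collar heights around 1 m).
    Collar heights are drawn N(mean, sd²) and recorded exactly in the ground
    truth along with every leaf area and per-point labels/plant ids.
    """
    if row_spacing <= 0 or n_plants < 1:
        raise InvalidParameterError("invalid plot parameters")
    rng = np.random.default_rng(seed)
    length = n_plants * in_row_spacing
    roi = (0.0, -row_spacing / 2.0, length, row_spacing / 2.0)

    clouds, plant_idx_parts, plant_gts = [], [], []
    heights = rng.normal(collar_height_mean, collar_height_sd, n_plants)
    heights = np.clip(heights, 0.5, None)  # crop stays above the weed band
    for i in range(n_plants):
        x = (i + 0.5) * in_row_spacing
        cloud, gt = make_plant(
            collar_height=float(heights[i]),
            n_leaves=n_leaves,
            leaf_length=leaf_length,
            leaf_width=leaf_width,
            points_per_m2=points_per_m2,
            seed=int(rng.integers(0, 2**31 - 1)),
            position=(x, 0.0),
        )
        clouds.append(cloud)
        plant_idx_parts.append(np.full(len(cloud), i, dtype=int))
        plant_gts.append(gt)

    # soil layer on z = 0
    n_soil = max(int(soil_points_per_m2 * (roi[2] - roi[0]) * (roi[3] - roi[1])), 100)
    soil_xy = rng.uniform([roi[0], roi[1]], [roi[2], roi[3]], size=(n_soil, 2))
    soil_pts = np.column_stack([soil_xy, np.zeros(n_soil)])
    soil_colors = np.tile(np.asarray(soil_color, np.uint8), (n_soil, 1))
    soil_cloud = PlantPointCloud(
        soil_pts, soil_colors, labels=np.full(n_soil, LABEL_SOIL, np.uint8)
    )
    clouds.append(soil_cloud)
    plant_idx_parts.append(np.full(n_soil, -1, dtype=int))

    # weed tufts: short green clusters scattered over the ROI
    if weed_fraction > 0:
        n_tufts = max(int(weed_fraction * n_plants * 3), 1)
        for _ in range(n_tufts):
            cx, cy = rng.uniform([roi[0], roi[1]], [roi[2], roi[3]])
            h = rng.uniform(0.05, 0.25)
            n_w = 60
            wx = rng.normal(cx, 0.03, n_w)
            wy = rng.normal(cy, 0.03, n_w)
            wz = rng.uniform(0.0, h, n_w)
            g = rng.integers(130, 190, n_w)
            w_colors = np.column_stack([g // 3, g, g // 3]).astype(np.uint8)
            weed_cloud = PlantPointCloud(
                np.column_stack([wx, wy, wz]),
                w_colors,
                labels=np.full(n_w, LABEL_WEED, np.uint8),
            )
            clouds.append(weed_cloud)
            plant_idx_parts.append(np.full(n_w, -1, dtype=int))

    points = np.vstack([c.points for c in clouds])
    colors = np.vstack([c.colors for c in clouds])
    labels = np.concatenate([c.labels for c in clouds])
    plant_index = np.concatenate(plant_idx_parts)
    cloud = PlantPointCloud(points, colors, labels=labels)
    gt = SceneGroundTruth(
        collar_heights=np.array([g.collar_height for g in plant_gts]),
        leaf_areas=[g.leaf_areas for g in plant_gts],
        plant_positions=np.array([g.position for g in plant_gts]),
        row_spacing=row_spacing,
        roi=roi,
        plant_index=plant_index,
        labels=labels,
        plants=plant_gts,
    )
    return cloud, gt


# ---------------------------------------------------------------------------
# thermal rendering and sensors
# ---------------------------------------------------------------------------

def look_down_pose(height: float = 6.0,
                   center_xy: tuple[float, float] = (0.0, 0.0)) -> RigidTransform:
    """Left-camera pose for a tower looking straight down at the field.

    Returns ``T_left_from_field``: camera +z points down (−z of the field),
    camera +x along field +x, at ``height`` meters above ``center_xy``.
    """
    # x_cam = R x_field + t with camera looking down:
    R = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, -1.0]])
    t = -R @ np.array([center_xy[0], center_xy[1], height])
    return RigidTransform(R, t)


def render_thermal(
    scene: PlantPointCloud,
    rig: StereoThermalRig,
    T_left_from_field: RigidTransform,
    leaf_temp: float = 24.0,
    soil_temp: float = 35.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> ThermalRaster:
    """Z-buffer render of a labeled scene into the thermal camera.

    Each scene point carries the temperature of its material (vegetation
    labels → ``leaf_temp``, soil → ``soil_temp``); the nearest point wins
    each pixel and unfilled background pixels read ``soil_temp``.  Gaussian
    sensor noise is added per pixel when requested.

    Raises
    ------
    EmptyInputError
        If no point projects in front of the thermal camera.
    """
    rng = np.random.default_rng(seed)
    pts_th = rig.T_thermal_from_left.apply(T_left_from_field.apply(scene.points))
    z = pts_th[:, 2]
    front = z > 0
    if not np.any(front):
        raise EmptyInputError("nothing visible: scene behind the thermal camera")
    w, h = rig.thermal.image_size
    values = np.full((h, w), float(soil_temp))
    px = project_points(pts_th[front], rig.thermal)
    inside = rig.thermal.contains(px)
    if np.any(inside):
        pxi = np.round(px[inside]).astype(int)
        zi = z[front][inside]
        if scene.labels is not None:
            temps = np.where(scene.labels[front][inside] == LABEL_SOIL,
                             float(soil_temp), float(leaf_temp))
        else:
            temps = np.full(inside.sum(), float(leaf_temp))
        order = np.argsort(zi)[::-1]  # nearest written last
        u, v = pxi[order, 0], pxi[order, 1]
        values[v, u] = temps[order]
    if noise_sigma > 0:
        values = values + rng.normal(0.0, noise_sigma, size=values.shape)
    return ThermalRaster(values=values)


_DEFAULT_RELATIONS = {
    "quantum_par": (1.0, 0.0),
    "photodiode_lux": (0.9, 2.0),
    "pyranometer": (0.5, 0.0),
}


def simulate_sensor_logs(
    irradiance: Sequence[float],
    relations: dict[str, tuple[float, float]] | None = None,
    noise: float = 0.1,
    seed: int = 0,
    start: str = "2016-07-01T10:00:00",
    cadence_s: float = 60.0,
    levels: Sequence[str] = ("ground", "mid", "top"),
    row: int = 1,
    plot: str = "A",
) -> list[SensorSeries]:
    """Sensor logs as affine responses to a shared true irradiance profile.

    Each (kind, level) sensor reports ``slope·irradiance + intercept + noise``
    in its native unit.  Lux photodiodes emit lux such that the standard
    0.0185 lux→PPFD conversion reproduces their configured PPFD relation —
    the relation an agreement analysis should recover.

    Raises
    ------
    InvalidParameterError
        Profile shorter than 2 samples.
    """
    profile = np.asarray(irradiance, dtype=float)
    if profile.ndim != 1 or len(profile) < 2:
        raise InvalidParameterError("irradiance profile needs >= 2 samples")
    rng = np.random.default_rng(seed)
    t0 = np.datetime64(start, "ns")
    ts = t0 + (np.arange(len(profile)) * int(cadence_s * 1e9)).astype(
        "timedelta64[ns]")
    rel = dict(_DEFAULT_RELATIONS)
    if relations:
        rel.update(relations)
    out = []
    for kind, (slope, intercept) in sorted(rel.items()):
        for level in levels:
            ideal = slope * profile + intercept
            vals = ideal + rng.normal(0.0, noise, len(profile))
            if kind == "photodiode_lux":
                vals = np.clip(vals, 0.0, None) / LUX_TO_PPFD
            else:
                vals = np.clip(vals, 0.0, None)
            out.append(
                SensorSeries(
                    sensor_id=f"{kind}_{level}",
                    kind=kind,
                    level=level,
                    row=row,
                    plot=plot,
                    timestamps=ts.copy(),
                    values=vals,
                )
            )
    return out
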
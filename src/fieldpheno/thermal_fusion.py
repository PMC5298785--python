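"""RGB↔thermal co-registration checks and temperature attachment.

Registration quality is validated by the three-step procedure used in the
field: (1) triangulate calibration-board corners from the left/right RGB
views, (2) re-project the 3D corners into the thermal image through the
calibrated rig, and (3) compare the re-projections with the corners observed
in the thermal image.  The report separates RMS from per-axis signed bias so
that a systematic (e.g., vertical) registration offset is visible and can be
subtracted.

Temperatures are attached to 3D points by projecting each point into the
thermal raster and sampling it (bilinear by default); points that fall
outside the raster, behind the camera, or behind a nearer point in the same
pixel bin receive a NaN sentinel and are excluded from statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .camera_geometry import (
    ReprojectionReport,
    RigidTransform,
    StereoThermalRig,
    project_points,
    reprojection_error_report,
    triangulate_pair,
)
from .canopy_traits import PlantPointCloud
from .errors import EmptyInputError, InvalidParameterError, NoOverlapError

__all__ = [
    "ThermalRaster",
    "RegistrationReport",
    "validate_registration",
    "map_temperature_to_cloud",
    "plot_mean_temperature",
]

#: a registration report is a reprojection report with its n_points field
RegistrationReport = ReprojectionReport


@dataclass
class ThermalRaster:
    """Grid of temperatures in °C as seen by the thermal camera."""

    values: np.ndarray
    timestamp: str = ""
    valid_range: tuple[float, float] = (-20.0, 80.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidParameterError("thermal raster must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("thermal raster must be finite")
        lo, hi = self.valid_range
        if self.values.min() < lo or self.values.max() > hi:
            raise InvalidParameterError(
                f"temperatures outside physical range [{lo}, {hi}] °C"
            )

    @property
    def image_size(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        h, w = self.values.shape
        return (w, h)


def validate_registration(
    corners_left: Mapping[int, tuple[float, float]],
    corners_right: Mapping[int, tuple[float, float]],
    corners_thermal: Mapping[int, tuple[float, float]],
    rig: StereoThermalRig,
) -> RegistrationReport:
    """Three-step stereo→thermal registration check on shared board corners.

    Corners present in all three cameras are triangulated from the RGB pair,
    re-projected into the thermal camera, and compared against the observed
    thermal corners.  The residual convention is observed − reprojected, so a
    thermal image shifted down by 2 px reports ``bias_v = 2``.

    Raises
    ------
    NoOverlapError
        If no corner id is shared by all three cameras.
    """
    shared = sorted(set(corners_left) & set(corners_right) & set(corners_thermal))
    if not shared:
        raise NoOverlapError("no corner ids shared by left, right and thermal")
    pts3d = np.array(
        [triangulate_pair(corners_left[i], corners_right[i], rig) for i in shared]
    )
    pts_th = rig.T_thermal_from_left.apply(pts3d)
    predicted = project_points(pts_th, rig.thermal)
    observed = np.array([corners_thermal[i] for i in shared], dtype=float)
    return reprojection_error_report(predicted, observed)


def map_temperature_to_cloud(
    cloud: PlantPointCloud,
    raster: ThermalRaster,
    rig: StereoThermalRig,
    T_left_from_field: RigidTransform,
    interpolation: str = "bilinear",
    zbuffer: bool = True,
) -> tuple[PlantPointCloud, dict]:
    """Attach a temperature to every cloud point visible in the thermal image.

    Each point is mapped field → left → thermal frame, projected, and the
    raster is sampled at the resulting pixel.  Points behind the camera or
    projecting outside the raster get NaN.  With ``zbuffer`` enabled only the
    nearest point within each integer pixel bin keeps its temperature; the
    occluded ones get NaN.

    Returns the augmented cloud plus a dict with assigned/excluded counts.

    Raises
    ------
    EmptyInputError
        On an empty cloud (guarded by PlantPointCloud itself).
    """
    if interpolation not in ("bilinear", "nearest"):
        raise InvalidParameterError(f"unknown interpolation {interpolation!r}")
    pts_th = rig.T_thermal_from_left.apply(T_left_from_field.apply(cloud.points))
    n = len(pts_th)
    temps = np.full(n, np.nan)
    z = pts_th[:, 2]
    front = z > 0
    w, h = raster.image_size
    if np.any(front):
        px = project_points(pts_th[front], rig.thermal)
        inside = (
            (px[:, 0] >= 0) & (px[:, 0] <= w - 1)
            & (px[:, 1] >= 0) & (px[:, 1] <= h - 1)
        )
        idx_front = np.where(front)[0]
        idx_vis = idx_front[inside]
        px_vis = px[inside]
        if zbuffer and len(idx_vis):
            keep = _zbuffer_keep(px_vis, z[idx_vis])
            idx_vis = idx_vis[keep]
            px_vis = px_vis[keep]
        if len(idx_vis):
            temps[idx_vis] = _sample(raster.values, px_vis, interpolation)
    out = PlantPointCloud(cloud.points, cloud.colors, temps, cloud.labels)
    assigned = int(np.isfinite(temps).sum())
    return out, {"n_assigned": assigned, "n_excluded": n - assigned}


def _zbuffer_keep(pixels: np.ndarray, depth: np.ndarray) -> np.ndarray:
    """Indices of the nearest point per integer pixel bin."""
    bins = np.round(pixels).astype(int)
    order = np.lexsort((depth, bins[:, 1], bins[:, 0]))
    sb = bins[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = np.any(sb[1:] != sb[:-1], axis=1)
    return order[first]


def _sample(values: np.ndarray, pixels: np.ndarray, interpolation: str) -> np.ndarray:
    h, w = values.shape
    u, v = pixels[:, 0], pixels[:, 1]
    if interpolation == "nearest":
        iu = np.clip(np.round(u).astype(int), 0, w - 1)
        iv = np.clip(np.round(v).astype(int), 0, h - 1)
        return values[iv, iu]
    u0 = np.clip(np.floor(u).astype(int), 0, w - 1)
    v0 = np.clip(np.floor(v).astype(int), 0, h - 1)
    u1 = np.minimum(u0 + 1, w - 1)
    v1 = np.minimum(v0 + 1, h - 1)
    fu = np.clip(u - u0, 0.0, 1.0)
    fv = np.clip(v - v0, 0.0, 1.0)
    return (
        values[v0, u0] * (1 - fu) * (1 - fv)
        + values[v0, u1] * fu * (1 - fv)
        + values[v1, u0] * (1 - fu) * fv
        + values[v1, u1] * fu * fv
    )


def plot_mean_temperature(
    raster: ThermalRaster, roi: tuple[float, float, float, float]
) -> float:
    """Mean of all raster pixels inside an axis-aligned bounding box.

    ``roi`` is ``(umin, vmin, umax, vmax)`` in pixels; a pixel belongs to the
    box when its center falls inside (boundary centers included).

    Raises
    ------
    EmptyInputError
        If the box contains no pixel centers.
    """
    umin, vmin, umax, vmax = roi
    w, h = raster.image_size
    u0 = max(int(np.ceil(umin)), 0)
    v0 = max(int(np.ceil(vmin)), 0)
    u1 = min(int(np.floor(umax)), w - 1)
    v1 = min(int(np.floor(vmax)), h - 1)
    if u1 < u0 or v1 < v0:
        raise EmptyInputError("roi outside raster")
    return float(raster.values[v0 : v1 + 1, u0 : u1 + 1].mean())


def leaf_mean_temperature(cloud: PlantPointCloud, label: int = 1) -> float:
    """Mean temperature of points carrying a given segment label (3D route).

    Complements :func:`plot_mean_temperature` (the raw 2D-box average used
    for plot statistics) with a mask-based, leaf-only alternative; NaN
    temperatures are excluded.
    """
    if cloud.temperature is None or cloud.labels is None:
        raise InvalidParameterError("cloud needs temperature and labels")
    sel = (cloud.labels == label) & np.isfinite(cloud.temperature)
    if not np.any(sel):
        raise EmptyInputError("no labeled points with temperatures")
    return float(cloud.temperature[sel].mean())
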
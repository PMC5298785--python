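"""Point-cloud trait extraction: plant height, growth rate and two LAI routes.

Heights follow the field definition used in manual phenotyping: the distance
from the ground to the collar of the topmost leaf.  Two leaf-area-index
estimators are provided:

* ``leaf_area_lai`` — the direct definition LAI = ΣSi / A, summing
  single-sided leaf surfaces over the ground area available per plant;
* ``lai_from_gap`` — the gap-fraction route LAI = −2·ln(P0), where P0 is the
  vertical gap fraction of a simulated top-down view of the segmented crop.

The −2 coefficient is the spherical leaf-angle special case of the
Beer–Lambert extinction law and is deliberately not configurable.  Because
overlapping leaves hide one another in a vertical view, the gap-fraction
estimate systematically undershoots the direct leaf-sum estimate on dense
canopies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .errors import (
    EmptyInputError,
    InvalidParameterError,
    NoPlaneError,
    NoPlantError,
    SaturatedCanopyError,
)

__all__ = [
    "PlantPointCloud",
    "GroundPlane",
    "OccupancyGrid",
    "TraitRecord",
    "LABEL_SOIL",
    "LABEL_CROP",
    "LABEL_WEED",
    "fit_ground_plane",
    "plant_height",
    "plot_height",
    "segment_canopy",
    "excess_green",
    "orthographic_occupancy",
    "gap_fraction",
    "lai_from_gap",
    "leaf_area_lai",
    "growth_rate",
]

LABEL_SOIL = 0
LABEL_CROP = 1
LABEL_WEED = 2

#: sentinel for missing per-point temperature
TEMP_MISSING = np.nan


@dataclass
class PlantPointCloud:
    """Metric 3D points with color and optional temperature / label channels.

    Field frame, +z up, coordinates in meters; colors are 8-bit RGB.
    """

    points: np.ndarray
    colors: np.ndarray | None = None
    temperature: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise InvalidParameterError("points must be (n, 3)")
        if len(self.points) < 1:
            raise EmptyInputError("point cloud must contain at least one point")
        if not np.all(np.isfinite(self.points)):
            raise InvalidParameterError("point coordinates must be finite")
        if self.colors is not None:
            self.colors = np.asarray(self.colors)
            if self.colors.shape != (len(self.points), 3):
                raise InvalidParameterError("colors must be (n, 3)")
        if self.temperature is not None:
            self.temperature = np.asarray(self.temperature, dtype=float)
            if self.temperature.shape != (len(self.points),):
                raise InvalidParameterError("temperature must be (n,)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (len(self.points),):
                raise InvalidParameterError("labels must be (n,)")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def has_color(self) -> bool:
        return self.colors is not None

    def select(self, mask: np.ndarray) -> "PlantPointCloud":
        """Subset the cloud (and all optional channels) by a boolean mask."""
        return PlantPointCloud(
            self.points[mask],
            None if self.colors is None else self.colors[mask],
            None if self.temperature is None else self.temperature[mask],
            None if self.labels is None else self.labels[mask],
        )


@dataclass
class GroundPlane:
    """Plane n·x = offset with upward-oriented unit normal."""

    normal: np.ndarray
    offset: float
    inlier_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(self.normal)
        if abs(norm - 1.0) > 1e-12:
            raise InvalidParameterError("normal must be unit length")
        if self.normal[2] <= 0:
            raise InvalidParameterError("normal must point upward (+z)")

    def height_above(self, points: np.ndarray) -> np.ndarray:
        """Signed perpendicular distance of points above the plane, meters."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.normal - self.offset


@dataclass
class OccupancyGrid:
    """Binary top-down raster over a plot ROI.

    ``grid[row, col]``: row 0 sits at the ROI's minimum-y edge, column 0 at
    minimum-x; a cell is True when at least one crop point landed in it.
    """

    grid: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    extent: tuple[float, float]
    empty_roi: bool = False

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise InvalidParameterError("cell size must be positive")
        self.grid = np.asarray(self.grid, dtype=bool)
        ny = int(np.ceil(self.extent[1] / self.cell_size - 1e-12))
        nx = int(np.ceil(self.extent[0] / self.cell_size - 1e-12))
        if self.grid.shape != (ny, nx):
            raise InvalidParameterError(
                f"grid shape {self.grid.shape} inconsistent with extent/cell size"
            )


@dataclass
class TraitRecord:
    """One extracted trait value for one plot at one time point."""

    plot_id: str
    dap: int
    trait: Literal["height", "LAI_gap", "LAI_leafsum", "temperature"]
    value: float
    units: Literal["m", "dimensionless", "degC"]
    method: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise InvalidParameterError("trait value must be finite")


# ---------------------------------------------------------------------------
# ground plane
# ---------------------------------------------------------------------------

def _plane_lstsq(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """Total least-squares plane through points; normal oriented +z."""
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    normal = vt[-1]
    if s[-2] < 1e-12 * max(s[0], 1.0):
        raise NoPlaneError("points are (near-)collinear")
    if normal[2] < 0:
        normal = -normal
    if normal[2] == 0:
        raise NoPlaneError("dominant plane is vertical; no ground surface")
    return normal, float(normal @ centroid)


def fit_ground_plane(
    cloud: PlantPointCloud,
    inlier_threshold: float = 0.02,
    min_inlier_fraction: float = 0.10,
    n_iterations: int = 500,
    seed: int = 0,
) -> GroundPlane:
    """RANSAC ground-plane fit with least-squares refinement on the inliers.

    Parameters
    ----------
    inlier_threshold : float
        Max perpendicular distance (m) for a point to count as ground.
    min_inlier_fraction : float
        Below this support the fit is rejected.

    Raises
    ------
    NoPlaneError
        Fewer than 3 points, collinear points, or insufficient support.
    """
    pts = cloud.points
    if len(pts) < 3:
        raise NoPlaneError("need at least 3 points to fit a plane")
    rng = np.random.default_rng(seed)
    best_inliers: np.ndarray | None = None
    best_count = -1
    for _ in range(n_iterations):
        idx = rng.choice(len(pts), size=3, replace=False)
        p0, p1, p2 = pts[idx]
        n = np.cross(p1 - p0, p2 - p0)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            continue
        n = n / norm
        if n[2] < 0:
            n = -n
        if n[2] <= 0:
            continue
        d = np.abs(pts @ n - n @ p0)
        inliers = d < inlier_threshold
        count = int(inliers.sum())
        if count > best_count:
            best_count = count
            best_inliers = inliers
    if best_inliers is None or best_count < 3:
        raise NoPlaneError("no dominant plane")
    frac = best_count / len(pts)
    if frac < min_inlier_fraction:
        raise NoPlaneError(
            f"no dominant plane: inlier fraction {frac:.2f} < {min_inlier_fraction}"
        )
    normal, offset = _plane_lstsq(pts[best_inliers])
    # one refinement pass with the refined plane's inliers
    d = np.abs(pts @ normal - offset)
    inliers = d < inlier_threshold
    if inliers.sum() >= 3:
        normal, offset = _plane_lstsq(pts[inliers])
        frac = float(inliers.mean())
    return GroundPlane(normal, offset, frac)


# ---------------------------------------------------------------------------
# heights
# ---------------------------------------------------------------------------

def plant_height(
    cloud: PlantPointCloud,
    ground: GroundPlane,
    mode: str = "auto",
    collar_point: np.ndarray | None = None,
    stem_band_fraction: float = 0.20,
    stem_radius: float = 0.03,
) -> float:
    """Height of one plant above the ground plane, meters.

    ``annotated`` mode reproduces the manual protocol exactly: the height is
    the perpendicular distance from a user-supplied collar point (the junction
    of the topmost leaf with the stem) to the ground plane.  ``auto`` mode is
    a collar proxy for unannotated clouds: the stem axis is taken as the
    vertical line through the 2D centroid of the lowest ``stem_band_fraction``
    height band, and the height of the topmost point within ``stem_radius``
    of that axis is returned.

    Raises
    ------
    NoPlantError
        If no points lie above the ground plane.
    """
    if mode == "annotated":
        if collar_point is None:
            raise InvalidParameterError("annotated mode requires a collar point")
        return float(ground.height_above(np.asarray(collar_point, float))[0])
    if mode != "auto":
        raise InvalidParameterError(f"unknown height mode {mode!r}")

    h = ground.height_above(cloud.points)
    above = h > 0
    if not np.any(above):
        raise NoPlantError("no points above the ground plane")
    pts = cloud.points[above]
    h = h[above]
    hmax = h.max()
    band = h <= stem_band_fraction * hmax
    if not np.any(band):
        band = np.ones(len(h), dtype=bool)
    axis_xy = pts[band, :2].mean(axis=0)
    r = np.linalg.norm(pts[:, :2] - axis_xy, axis=1)
    near_axis = r < stem_radius
    if not np.any(near_axis):
        near_axis = np.ones(len(h), dtype=bool)
    return float(h[near_axis].max())


def plot_height(
    heights_or_clouds: Sequence,
    ground: GroundPlane | None = None,
    **height_kwargs,
) -> dict:
    """Plot-level height: the mean of per-plant heights within one plot.

    Accepts either precomputed per-plant heights (floats) or per-plant clouds
    (in which case ``ground`` is required and :func:`plant_height` is applied
    to each).

    Returns
    -------
    dict with ``mean`` (m), ``sd``, ``per_plant`` and ``n``.
    """
    if len(heights_or_clouds) == 0:
        raise EmptyInputError("no plants in plot")
    per_plant = []
    for item in heights_or_clouds:
        if isinstance(item, PlantPointCloud):
            if ground is None:
                raise InvalidParameterError("ground plane required for clouds")
            per_plant.append(plant_height(item, ground, **height_kwargs))
        else:
            per_plant.append(float(item))
    arr = np.asarray(per_plant)
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        "per_plant": per_plant,
        "n": len(arr),
    }


def growth_rate(records: Sequence[tuple[float, float]]) -> dict:
    """Least-squares growth rate from (DAP, height) pairs, m/day.

    Raises
    ------
    InvalidParameterError
        Fewer than 2 distinct DAP values.
    """
    arr = np.asarray(records, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(np.unique(arr[:, 0])) < 2:
        raise InvalidParameterError("need >= 2 distinct time points")
    dap, h = arr[:, 0], arr[:, 1]
    A = np.column_stack([dap, np.ones_like(dap)])
    (slope, intercept), res, *_ = np.linalg.lstsq(A, h, rcond=None)
    fitted = A @ [slope, intercept]
    dof = max(len(h) - 2, 1)
    resid_sd = float(np.sqrt(np.sum((h - fitted) ** 2) / dof))
    return {"slope": float(slope), "intercept": float(intercept),
            "residual_sd": resid_sd, "n": len(h)}


# ---------------------------------------------------------------------------
# segmentation and gap-fraction LAI
# ---------------------------------------------------------------------------

def excess_green(colors: np.ndarray) -> np.ndarray:
    """Excess-green vegetation index ExG = 2G − R − B on 8-bit colors."""
    c = np.asarray(colors, dtype=float)
    return 2.0 * c[:, 1] - c[:, 0] - c[:, 2]


def segment_canopy(
    cloud: PlantPointCloud,
    ground: GroundPlane,
    color_threshold: float = 20.0,
    height_threshold: float | str = 0.3,
) -> tuple[PlantPointCloud, dict]:
    """Label each point as soil, crop or weed using color plus height.

    Soil is anything whose excess-green index falls below ``color_threshold``.
    Green points are then split by height above ground: weeds sit below
    ``height_threshold`` (weeds in row crops form a distinctly lower height
    mode than the crop), the remainder is crop.  ``height_threshold='auto'``
    places the split at the Otsu threshold of the green-point heights when the
    histogram is bimodal enough to support one.

    Returns the labeled cloud plus a summary dict (counts, threshold used,
    ``no_green`` warning flag).
    """
    if not cloud.has_color:
        raise InvalidParameterError("segmentation requires per-point colors")
    exg = excess_green(cloud.colors)
    green = exg >= color_threshold
    labels = np.full(len(cloud), LABEL_SOIL, dtype=np.uint8)
    info: dict = {"no_green": False, "height_threshold": None}
    if not np.any(green):
        info["no_green"] = True
    else:
        h = ground.height_above(cloud.points[green])
        if height_threshold == "auto":
            thr = _auto_height_split(h)
        else:
            thr = float(height_threshold)
        info["height_threshold"] = thr
        sub = np.where(green)[0]
        labels[sub[h < thr]] = LABEL_WEED
        labels[sub[h >= thr]] = LABEL_CROP
    out = PlantPointCloud(cloud.points, cloud.colors, cloud.temperature, labels)
    info.update(
        n_soil=int((labels == LABEL_SOIL).sum()),
        n_crop=int((labels == LABEL_CROP).sum()),
        n_weed=int((labels == LABEL_WEED).sum()),
    )
    return out, info


def _auto_height_split(heights: np.ndarray) -> float:
    """Otsu split of green-point heights; falls back to 0.3 m if unimodal."""
    if len(np.unique(np.round(heights, 6))) < 3:
        return 0.3
    thr = float(threshold_otsu(heights, nbins=128))
    lo = heights[heights < thr]
    hi = heights[heights >= thr]
    if len(lo) == 0 or len(hi) == 0:
        return 0.3
    # accept the split only when the two modes are clearly separated
    spread = heights.std()
    if spread == 0 or (hi.mean() - lo.mean()) < spread:
        return 0.3
    return thr


def orthographic_occupancy(
    cloud: PlantPointCloud,
    roi: tuple[float, float, float, float],
    cell_size: float = 0.01,
) -> OccupancyGrid:
    """Top-down binary occupancy of crop points over a field-frame ROI.

    The z coordinate is dropped (orthogonal re-projection) and each point is
    binned into a ``cell_size`` grid covering exactly the ROI
    ``(xmin, ymin, xmax, ymax)``; a cell is foreground when it captured at
    least one point.  Points outside the ROI are ignored.
    """
    xmin, ymin, xmax, ymax = roi
    if xmax <= xmin or ymax <= ymin:
        raise InvalidParameterError("ROI must have positive area")
    if cell_size <= 0:
        raise InvalidParameterError("cell size must be positive")
    nx = int(np.ceil((xmax - xmin) / cell_size - 1e-12))
    ny = int(np.ceil((ymax - ymin) / cell_size - 1e-12))
    grid = np.zeros((ny, nx), dtype=bool)
    pts = cloud.points
    inside = (
        (pts[:, 0] >= xmin)
        & (pts[:, 0] < xmax)
        & (pts[:, 1] >= ymin)
        & (pts[:, 1] < ymax)
    )
    sel = pts[inside]
    if len(sel):
        ix = np.minimum(((sel[:, 0] - xmin) / cell_size).astype(int), nx - 1)
        iy = np.minimum(((sel[:, 1] - ymin) / cell_size).astype(int), ny - 1)
        grid[iy, ix] = True
    return OccupancyGrid(
        grid=grid,
        cell_size=cell_size,
        origin=(xmin, ymin),
        extent=(xmax - xmin, ymax - ymin),
        empty_roi=not np.any(inside),
    )


def gap_fraction(grid: OccupancyGrid) -> float:
    """Vertical gap fraction P0 = background cells / total cells."""
    total = grid.grid.size
    if total == 0:
        raise EmptyInputError("empty grid")
    return float((total - grid.grid.sum()) / total)


def lai_from_gap(p0: float) -> float:
    """Gap-fraction LAI estimate, LAI = −2·ln(P0).

    The coefficient 2 is the inverse nadir extinction coefficient for a
    spherical leaf-angle distribution.

    Raises
    ------
    SaturatedCanopyError
        P0 = 0 (no visible background; the estimate diverges).
    InvalidParameterError
        P0 outside (0, 1].
    """
    if p0 == 0:
        raise SaturatedCanopyError("saturated canopy: gap fraction is zero")
    if not (0.0 < p0 <= 1.0):
        raise InvalidParameterError(f"gap fraction {p0} outside (0, 1]")
    lai = -2.0 * np.log(p0)
    return float(lai) if lai != 0 else 0.0


def leaf_area_lai(
    leaf_surfaces: Sequence[float] | Sequence[np.ndarray],
    ground_area: float,
) -> float:
    """Direct leaf-sum LAI = Σ Si / A.

    ``leaf_surfaces`` holds one entry per leaf: either a single-sided area in
    m², or an (m, 3, 3) array of mesh triangles whose summed area is used.

    Raises
    ------
    InvalidParameterError
        Non-positive ground area or negative leaf area.
    """
    if ground_area <= 0:
        raise InvalidParameterError("invalid ground area")
    total = 0.0
    for s in leaf_surfaces:
        if np.ndim(s) == 0:
            a = float(s)
            if a < 0:
                raise InvalidParameterError("leaf areas must be >= 0")
            total += a
        else:
            tris = np.asarray(s, dtype=float)
            if tris.ndim != 3 or tris.shape[1:] != (3, 3):
                raise InvalidParameterError("triangle patch must be (m, 3, 3)")
            e1 = tris[:, 1] - tris[:, 0]
            e2 = tris[:, 2] - tris[:, 0]
            total += float(0.5 * np.linalg.norm(np.cross(e1, e2), axis=1).sum())
    return total / ground_area
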
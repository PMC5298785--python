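"""Readers and writers for the pipeline's on-disk formats.

Formats: PLY point clouds (binary little-endian written, ASCII accepted on
read; properties x, y, z, red, green, blue, optional float32 ``temperature``
and uchar ``label``), corner-observation and sensor-log CSVs, rig/scene YAML,
16-bit thermal TIFFs with a YAML sidecar carrying the linear DN→°C scale,
and versioned results JSON.

All coordinates on disk are meters in the field frame (+z up).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.spatial.transform import Rotation

from .camera_geometry import CameraIntrinsics, RigidTransform, StereoThermalRig
from .canopy_traits import PlantPointCloud, TraitRecord
from .env_sensors import SensorSeries
from .errors import InvalidParameterError, ParseError
from .thermal_fusion import ThermalRaster

__all__ = [
    "read_cloud",
    "write_cloud",
    "read_corner_csv",
    "write_corner_csv",
    "read_sensor_log",
    "write_sensor_log",
    "load_rig",
    "save_rig",
    "read_thermal",
    "write_thermal",
    "write_trait_records",
    "write_results",
    "RunConfig",
]

RESULTS_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# PLY point clouds
# ---------------------------------------------------------------------------

_PLY_TYPES = {
    "float": ("<f4", 4), "float32": ("<f4", 4),
    "double": ("<f8", 8), "float64": ("<f8", 8),
    "uchar": ("<u1", 1), "uint8": ("<u1", 1),
    "char": ("<i1", 1), "int8": ("<i1", 1),
    "ushort": ("<u2", 2), "uint16": ("<u2", 2),
    "short": ("<i2", 2), "int16": ("<i2", 2),
    "uint": ("<u4", 4), "uint32": ("<u4", 4),
    "int": ("<i4", 4), "int32": ("<i4", 4),
}


def write_cloud(cloud: PlantPointCloud, path: str | Path) -> None:
    """Write a cloud as binary little-endian PLY.

    Always writes x/y/z as float64; colors, temperature and label properties
    are included when present so the read/write round trip is lossless.
    """
    path = Path(path)
    n = len(cloud)
    props = [("x", "double"), ("y", "double"), ("z", "double")]
    if cloud.colors is not None:
        props += [("red", "uchar"), ("green", "uchar"), ("blue", "uchar")]
    if cloud.temperature is not None:
        props.append(("temperature", "float"))
    if cloud.labels is not None:
        props.append(("label", "uchar"))
    header = ["ply", "format binary_little_endian 1.0",
              f"element vertex {n}"]
    header += [f"property {t} {name}" for name, t in props]
    header.append("end_header")

    dtype = np.dtype([(name, _PLY_TYPES[t][0]) for name, t in props])
    rec = np.empty(n, dtype=dtype)
    rec["x"], rec["y"], rec["z"] = cloud.points.T
    if cloud.colors is not None:
        rec["red"] = cloud.colors[:, 0]
        rec["green"] = cloud.colors[:, 1]
        rec["blue"] = cloud.colors[:, 2]
    if cloud.temperature is not None:
        rec["temperature"] = cloud.temperature.astype(np.float32)
    if cloud.labels is not None:
        rec["label"] = cloud.labels.astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        fh.write(rec.tobytes())


def read_cloud(path: str | Path) -> PlantPointCloud:
    """Read a PLY point cloud (binary little-endian or ASCII).

    Raises
    ------
    ParseError
        Malformed header, unsupported format, or truncated data.
    """
    path = Path(path)
    raw = path.read_bytes()
    try:
        end = raw.index(b"end_header\n")
    except ValueError:
        raise ParseError(f"{path}: missing end_header")
    header = raw[:end].decode("ascii", errors="replace").splitlines()
    body = raw[end + len(b"end_header\n"):]
    if not header or header[0].strip() != "ply":
        raise ParseError(f"{path}: not a PLY file (missing 'ply' magic)")
    fmt = None
    n_vertex = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    for lineno, line in enumerate(header[1:], start=2):
        tok = line.split()
        if not tok or tok[0] == "comment":
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                n_vertex = int(tok[2])
        elif tok[0] == "property" and in_vertex:
            if tok[1] == "list":
                raise ParseError(f"{path}:{lineno}: list properties unsupported")
            if tok[1] not in _PLY_TYPES:
                raise ParseError(f"{path}:{lineno}: unknown type {tok[1]!r}")
            props.append((tok[2], tok[1]))
    if fmt not in ("binary_little_endian", "ascii"):
        raise ParseError(f"{path}: unsupported format {fmt!r}")
    if n_vertex is None:
        raise ParseError(f"{path}: no vertex element")
    names = [p[0] for p in props]
    for req in ("x", "y", "z"):
        if req not in names:
            raise ParseError(f"{path}: required property {req!r} missing")

    dtype = np.dtype([(name, _PLY_TYPES[t][0]) for name, t in props])
    if fmt == "binary_little_endian":
        expected = n_vertex * dtype.itemsize
        if len(body) < expected:
            raise ParseError(
                f"{path}: truncated data — expected {n_vertex} vertices "
                f"({expected} bytes), found {len(body)}"
            )
        rec = np.frombuffer(body[:expected], dtype=dtype)
    else:
        rows = body.decode("ascii").split()
        expected = n_vertex * len(props)
        if len(rows) < expected:
            raise ParseError(
                f"{path}: truncated data — expected {n_vertex} vertices "
                f"({expected} values), found {len(rows)}"
            )
        arr = np.array(rows[:expected], dtype=float).reshape(n_vertex, len(props))
        rec = np.empty(n_vertex, dtype=dtype)
        for i, (name, _) in enumerate(props):
            rec[name] = arr[:, i]

    points = np.column_stack([rec["x"], rec["y"], rec["z"]]).astype(float)
    colors = None
    if all(c in names for c in ("red", "green", "blue")):
        colors = np.column_stack(
            [rec["red"], rec["green"], rec["blue"]]).astype(np.uint8)
    temperature = rec["temperature"].astype(float) if "temperature" in names else None
    labels = rec["label"].astype(np.uint8) if "label" in names else None
    return PlantPointCloud(points, colors, temperature, labels)


# ---------------------------------------------------------------------------
# corner CSVs
# ---------------------------------------------------------------------------

def write_corner_csv(
    observations: Mapping[str, Sequence[Mapping[int, tuple[float, float]]]],
    path: str | Path,
) -> None:
    """Write per-view corner observations: view_id,camera,corner_id,u,v."""
    rows = []
    for camera in sorted(observations):
        for view_id, obs in enumerate(observations[camera]):
            for cid in sorted(obs):
                u, v = obs[cid]
                rows.append((view_id, camera, cid, repr(float(u)), repr(float(v))))
    df = pd.DataFrame(rows, columns=["view_id", "camera", "corner_id", "u", "v"])
    df.to_csv(path, index=False)


def read_corner_csv(
    path: str | Path,
) -> dict[str, list[dict[int, tuple[float, float]]]]:
    """Read corner observations grouped as observations[camera][view]."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"view_id", "camera", "corner_id", "u", "v"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: corner CSV needs columns {sorted(required)}")
    out: dict[str, list[dict[int, tuple[float, float]]]] = {}
    n_views = int(df["view_id"].max()) + 1 if len(df) else 0
    for camera, grp in df.groupby("camera"):
        views: list[dict[int, tuple[float, float]]] = [{} for _ in range(n_views)]
        for _, r in grp.iterrows():
            views[int(r.view_id)][int(r.corner_id)] = (float(r.u), float(r.v))
        out[str(camera)] = views
    return out


# ---------------------------------------------------------------------------
# sensor logs
# ---------------------------------------------------------------------------

_SENSOR_COLUMNS = ["timestamp_iso8601", "row", "plot", "level",
                   "sensor_id", "kind", "value", "units"]


def write_sensor_log(series: Sequence[SensorSeries], path: str | Path) -> None:
    """Write a sensor-series collection to the documented CSV layout."""
    rows = []
    for s in series:
        for t, v in zip(s.timestamps, s.values):
            iso = np.datetime_as_string(t, unit="s")
            rows.append((iso, s.row, s.plot, s.level, s.sensor_id, s.kind,
                         repr(float(v)), s.units))
    pd.DataFrame(rows, columns=_SENSOR_COLUMNS).to_csv(path, index=False)


def read_sensor_log(path: str | Path) -> list[SensorSeries]:
    """Read sensor logs, grouping rows by sensor_id.

    Raises
    ------
    ParseError
        Wrong header, non-monotone timestamps (names the sensor and row),
        or a unit/kind mismatch.
    """
    df = pd.read_csv(path, dtype={"plot": str}, float_precision="round_trip")
    if list(df.columns) != _SENSOR_COLUMNS:
        raise ParseError(f"{path}: expected header {','.join(_SENSOR_COLUMNS)}")
    try:
        df["ts"] = pd.to_datetime(df["timestamp_iso8601"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: bad timestamp ({exc})")
    out = []
    for sensor_id, grp in df.groupby("sensor_id", sort=True):
        ts = grp["ts"].to_numpy()
        bad = np.where(np.diff(ts) <= np.timedelta64(0, "ns"))[0]
        if len(bad):
            row_no = grp.index[bad[0] + 1] + 2  # header + 1-based
            raise ParseError(
                f"{path}: non-monotone timestamp for sensor {sensor_id} "
                f"at line {row_no}"
            )
        kinds = grp["kind"].unique()
        units = grp["units"].unique()
        if len(kinds) != 1 or len(units) != 1:
            raise ParseError(f"{path}: sensor {sensor_id} mixes kinds/units")
        try:
            out.append(
                SensorSeries(
                    sensor_id=str(sensor_id),
                    kind=str(kinds[0]),
                    level=str(grp["level"].iloc[0]),
                    row=int(grp["row"].iloc[0]),
                    plot=str(grp["plot"].iloc[0]),
                    timestamps=ts,
                    values=grp["value"].to_numpy(dtype=float),
                    units=str(units[0]),
                )
            )
        except InvalidParameterError as exc:
            raise ParseError(f"{path}: {exc}")
    return out


# ---------------------------------------------------------------------------
# rig YAML
# ---------------------------------------------------------------------------

def _intrinsics_to_dict(cam: CameraIntrinsics) -> dict:
    k1, k2, p1, p2, k3 = (float(x) for x in cam.dist)
    return {
        "fx": float(cam.fx), "fy": float(cam.fy),
        "cx": float(cam.cx), "cy": float(cam.cy), "skew": float(cam.skew),
        "k1": k1, "k2": k2, "p1": p1, "p2": p2, "k3": k3,
        "width": int(cam.image_size[0]), "height": int(cam.image_size[1]),
    }


def _intrinsics_from_dict(d: Mapping) -> CameraIntrinsics:
    return CameraIntrinsics(
        fx=d["fx"], fy=d["fy"], cx=d["cx"], cy=d["cy"], skew=d.get("skew", 0.0),
        dist=np.array([d.get(k, 0.0) for k in ("k1", "k2", "p1", "p2", "k3")]),
        image_size=(int(d["width"]), int(d["height"])),
    )


def _transform_to_dict(t: RigidTransform) -> dict:
    q = Rotation.from_matrix(t.rotation).as_quat()  # xyzw
    return {
        "quaternion_wxyz": [float(q[3]), float(q[0]), float(q[1]), float(q[2])],
        "translation_xyz_m": [float(x) for x in t.translation],
    }


def _transform_from_dict(d: Mapping) -> RigidTransform:
    w, x, y, z = d["quaternion_wxyz"]
    rot = Rotation.from_quat([x, y, z, w]).as_matrix()
    return RigidTransform(rot, np.asarray(d["translation_xyz_m"], float))


def save_rig(rig: StereoThermalRig, path: str | Path) -> None:
    """Serialize a calibrated rig to YAML (quaternion wxyz + translation)."""
    doc = {
        "left": _intrinsics_to_dict(rig.left),
        "right": _intrinsics_to_dict(rig.right),
        "thermal": _intrinsics_to_dict(rig.thermal),
        "T_right_from_left": _transform_to_dict(rig.T_right_from_left),
        "T_thermal_from_left": _transform_to_dict(rig.T_thermal_from_left),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_rig(path: str | Path) -> StereoThermalRig:
    """Load a rig YAML written by :func:`save_rig`."""
    doc = yaml.safe_load(Path(path).read_text())
    try:
        return StereoThermalRig(
            left=_intrinsics_from_dict(doc["left"]),
            right=_intrinsics_from_dict(doc["right"]),
            thermal=_intrinsics_from_dict(doc["thermal"]),
            T_right_from_left=_transform_from_dict(doc["T_right_from_left"]),
            T_thermal_from_left=_transform_from_dict(doc["T_thermal_from_left"]),
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: malformed rig file ({exc})")


# ---------------------------------------------------------------------------
# thermal raster TIFF + sidecar
# ---------------------------------------------------------------------------

def write_thermal(raster: ThermalRaster, path: str | Path) -> None:
    """Write a 16-bit TIFF plus a YAML sidecar with the linear DN→°C map."""
    path = Path(path)
    lo = float(raster.values.min())
    hi = float(raster.values.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    dn = np.round((raster.values - lo) / scale).astype(np.uint16)
    tifffile.imwrite(path, dn)
    sidecar = {
        "scale_degC_per_DN": scale,
        "offset_degC": lo,
        "timestamp": raster.timestamp,
        "valid_range_degC": list(raster.valid_range),
    }
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(sidecar))


def read_thermal(path: str | Path) -> ThermalRaster:
    """Read a thermal TIFF with its YAML sidecar (°C = scale × DN + offset)."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".yaml")
    if not sidecar_path.exists():
        raise ParseError(f"{path}: missing sidecar {sidecar_path.name}")
    meta = yaml.safe_load(sidecar_path.read_text())
    dn = tifffile.imread(path).astype(float)
    values = meta["scale_degC_per_DN"] * dn + meta["offset_degC"]
    return ThermalRaster(
        values=values,
        timestamp=meta.get("timestamp", ""),
        valid_range=tuple(meta.get("valid_range_degC", (-20.0, 80.0))),
    )


# ---------------------------------------------------------------------------
# trait tables, results, run config
# ---------------------------------------------------------------------------

def write_trait_records(records: Sequence[TraitRecord], path: str | Path) -> None:
    """Write trait records as CSV: plot_id,dap,trait,value,units,method."""
    pd.DataFrame(
        [(r.plot_id, r.dap, r.trait, repr(float(r.value)), r.units, r.method)
         for r in records],
        columns=["plot_id", "dap", "trait", "value", "units", "method"],
    ).to_csv(path, index=False)


def write_results(payload: Mapping, path: str | Path) -> None:
    """Write a versioned results JSON with full float precision."""
    doc = {"schema_version": RESULTS_SCHEMA_VERSION, **payload}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


_CONFIG_KEYS = {
    "paths", "rig_file", "rois", "color_threshold", "height_threshold",
    "cell_size", "ransac_threshold", "pairing_tolerance_s", "seed",
    "output_dir",
}

_POSITIVE_KEYS = ("cell_size", "ransac_threshold", "pairing_tolerance_s")


class RunConfig(dict):
    """Validated run configuration loaded from YAML.

    Unknown keys are rejected; thresholds that must be positive are checked
    on load.
    """

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - _CONFIG_KEYS
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in _POSITIVE_KEYS:
            if key in doc and not (isinstance(doc[key], (int, float))
                                   and doc[key] > 0):
                raise ParseError(f"{path}: {key} must be a positive number")
        return cls(doc)
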
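"""Light-unit conversion and cross-sensor agreement statistics.

Lux readings from inexpensive photodiodes are converted to photosynthetic
photon flux density (PPFD, µmol·m⁻²·s⁻¹) with the sunlight factor 0.0185,
so they can be compared against quantum PAR sensors.  Agreement between any
two timestamped series (different sensors, heights, or platforms) is
summarised as RMSE against the y = x line, mean bias, the least-squares
line of a on b, and Pearson r, after pairing readings by nearest timestamp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidParameterError, NoOverlapError

__all__ = [
    "LUX_TO_PPFD",
    "SensorSeries",
    "AgreementStats",
    "lux_to_ppfd",
    "agreement_stats",
    "aggregate_by_plot",
]

#: sunlight conversion factor from lux to PPFD (µmol·m⁻²·s⁻¹ per lux)
LUX_TO_PPFD = 0.0185

_KIND_UNITS = {
    "quantum_par": "umol/m2/s",
    "pyranometer": "W/m2",
    "photodiode_lux": "lux",
    "air_temp": "degC",
    "ir_plot_temp": "degC",
    "humidity": "percent",
}


@dataclass
class SensorSeries:
    """One sensor's timestamped readings plus its field metadata."""

    sensor_id: str
    kind: str
    level: str = "top"
    row: int = 0
    plot: str = ""
    timestamps: np.ndarray = field(default_factory=lambda: np.array([], "datetime64[ns]"))
    values: np.ndarray = field(default_factory=lambda: np.array([]))
    units: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[ns]")
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise InvalidParameterError("timestamps and values must align")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps)
                                                   > np.timedelta64(0, "ns")):
            raise InvalidParameterError(
                f"timestamps of sensor {self.sensor_id} not strictly increasing"
            )
        if self.kind in _KIND_UNITS and self.units and \
                self.units != _KIND_UNITS[self.kind]:
            raise InvalidParameterError(
                f"units {self.units!r} inconsistent with kind {self.kind!r}"
            )
        if not self.units and self.kind in _KIND_UNITS:
            self.units = _KIND_UNITS[self.kind]

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class AgreementStats:
    """Pairwise agreement summary between two matched series."""

    rmse: float
    bias: float
    slope: float
    intercept: float
    pearson_r: float
    n: int
    n_unmatched_a: int = 0
    n_unmatched_b: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidParameterError("agreement needs >= 2 pairs")
        if self.rmse < 0 or (np.isfinite(self.pearson_r)
                             and abs(self.pearson_r) > 1 + 1e-12):
            raise InvalidParameterError("invalid agreement statistics")


def lux_to_ppfd(lux, factor: float = LUX_TO_PPFD):
    """Convert lux to PPFD (µmol·m⁻²·s⁻¹) with the sunlight factor 0.0185.

    Accepts a scalar, an array, or a :class:`SensorSeries` of kind
    ``photodiode_lux`` (returned as a new ``quantum_par``-unit series with
    identical timestamps).

    Raises
    ------
    InvalidParameterError
        On negative readings.
    """
    if isinstance(lux, SensorSeries):
        if np.any(lux.values < 0):
            raise InvalidParameterError("invalid reading: negative lux")
        return SensorSeries(
            sensor_id=lux.sensor_id,
            kind="quantum_par",
            level=lux.level,
            row=lux.row,
            plot=lux.plot,
            timestamps=lux.timestamps.copy(),
            values=lux.values * factor,
            units="umol/m2/s",
        )
    arr = np.asarray(lux, dtype=float)
    if np.any(arr < 0):
        raise InvalidParameterError("invalid reading: negative lux")
    out = arr * factor
    return float(out) if np.ndim(lux) == 0 else out


def _pair_by_timestamp(
    a: SensorSeries, b: SensorSeries, tolerance_s: float
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Match each reading of a to its nearest-in-time reading of b."""
    ta = a.timestamps.astype("datetime64[ns]").astype(np.int64)
    tb = b.timestamps.astype("datetime64[ns]").astype(np.int64)
    tol = int(tolerance_s * 1e9)
    idx = np.searchsorted(tb, ta)
    va, vb = [], []
    used_b: set[int] = set()
    for i, t in enumerate(ta):
        candidates = [j for j in (idx[i] - 1, idx[i]) if 0 <= j < len(tb)]
        if not candidates:
            continue
        j = min(candidates, key=lambda j: abs(tb[j] - t))
        if abs(tb[j] - t) <= tol:
            va.append(a.values[i])
            vb.append(b.values[j])
            used_b.add(j)
    return (np.asarray(va), np.asarray(vb),
            len(ta) - len(va), len(tb) - len(used_b))


def agreement_stats(
    a: SensorSeries | np.ndarray,
    b: SensorSeries | np.ndarray,
    tolerance_s: float = 60.0,
) -> AgreementStats:
    """Agreement between two series after nearest-timestamp pairing.

    RMSE and bias are computed on a − b (deviation from the y = x line);
    slope/intercept are the least-squares fit of a on b.  Plain arrays are
    treated as already paired.  Constant series cannot support a correlation
    and are flagged ``degenerate`` (r reported as NaN), except for the exact
    self-comparison case where r = 1 by convention.

    Raises
    ------
    NoOverlapError
        Fewer than 2 matched pairs.
    """
    if isinstance(a, SensorSeries) and isinstance(b, SensorSeries):
        va, vb, un_a, un_b = _pair_by_timestamp(a, b, tolerance_s)
    else:
        va = np.asarray(a, dtype=float)
        vb = np.asarray(b, dtype=float)
        if va.shape != vb.shape:
            raise InvalidParameterError("paired arrays must have equal length")
        un_a = un_b = 0
    if len(va) < 2:
        raise NoOverlapError("insufficient overlap: fewer than 2 matched pairs")
    diff = va - vb
    rmse = float(np.sqrt(np.mean(diff**2)))
    bias = float(np.mean(diff))
    sa, sb = va.std(), vb.std()
    degenerate = sa == 0 or sb == 0
    if degenerate:
        slope, intercept = 0.0, float(va.mean())
        r = 1.0 if np.array_equal(va, vb) else float("nan")
    else:
        slope, intercept = np.polyfit(vb, va, 1)
        r = float(np.corrcoef(va, vb)[0, 1])
    return AgreementStats(
        rmse=rmse,
        bias=bias,
        slope=float(slope),
        intercept=float(intercept),
        pearson_r=r,
        n=len(va),
        n_unmatched_a=un_a,
        n_unmatched_b=un_b,
        degenerate=degenerate,
    )


def aggregate_by_plot(series: Sequence[SensorSeries]) -> pd.DataFrame:
    """Mean/sd/n of readings grouped by (row, plot, level).

    Group ordering is deterministic: sorted by row, then plot, then level.

    Raises
    ------
    EmptyInputError
        On an empty collection.
    """
    if not series:
        raise EmptyInputError("no data")
    frames = [
        pd.DataFrame(
            {"row": s.row, "plot": s.plot, "level": s.level, "value": s.values}
        )
        for s in series
        if len(s)
    ]
    if not frames:
        raise EmptyInputError("no data")
    df = pd.concat(frames, ignore_index=True)
    out = (
        df.groupby(["row", "plot", "level"], sort=True)["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    return out
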
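"""Reading and writing IMU sessions, annotations and event tables.

Canonical units are m/s^2 for the accelerometer and rad/s for the
gyroscope.  The canonical axis order is (x, y, z) with x the vertical
(cranial) axis when standing, y the medio-lateral axis and z the
anterior-posterior axis.  Files produced elsewhere can be brought into
this convention with an :class:`AxisConvention` remap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, ValidationError

log = logging.getLogger(__name__)

IMU_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")
DIRECTIONS = ("SiSt", "StSi")

#: Maximum NaN run (seconds) repaired by linear interpolation.
MAX_NAN_GAP_S = 0.25
#: Tolerance (seconds) on the uniformity of the time grid.
TIME_STEP_TOL_S = 1e-6


@dataclass(frozen=True)
class AxisConvention:
    """Signed permutation taking file columns to canonical body axes.

    ``mapping`` lists, for each canonical axis (x, y, z), the source
    column as a string like ``"+x"``, ``"-z"`` ... referring to the file's
    own axis labels.
    """

    mapping: tuple[str, str, str] = ("+x", "+y", "+z")

    _IDX = {"x": 0, "y": 1, "z": 2}

    def _parse(self) -> tuple[np.ndarray, np.ndarray]:
        idx = np.empty(3, dtype=int)
        sign = np.empty(3)
        for i, spec in enumerate(self.mapping):
            s = spec.strip()
            if len(s) == 2 and s[0] in "+-" and s[1] in self._IDX:
                sign[i] = 1.0 if s[0] == "+" else -1.0
                idx[i] = self._IDX[s[1]]
            elif len(s) == 1 and s in self._IDX:
                sign[i] = 1.0
                idx[i] = self._IDX[s]
            else:
                raise ValidationError(f"bad axis spec {spec!r}")
        if sorted(idx) != [0, 1, 2]:
            raise ValidationError(f"axis mapping {self.mapping} is not a permutation")
        return idx, sign

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        """Remap an (n, 3) array from file axes to canonical axes."""
        idx, sign = self._parse()
        return xyz[:, idx] * sign

    def inverse(self) -> "AxisConvention":
        idx, sign = self._parse()
        inv = ["", "", ""]
        names = "xyz"
        for canon, (src, sg) in enumerate(zip(idx, sign)):
            inv[src] = ("+" if sg > 0 else "-") + names[canon]
        return AxisConvention(tuple(inv))  # type: ignore[arg-type]


IDENTITY_CONVENTION = AxisConvention()


@dataclass
class ImuRecording:
    """A uniformly sampled tri-axial accelerometer + gyroscope session.

    Attributes
    ----------
    sample_rate : float
        Samples per second (nominally 128).
    time : (n,) array
        Seconds, strictly increasing, uniform step ``1/sample_rate``.
    accel : (n, 3) array
        Raw acceleration, m/s^2, canonical axis order.
    gyro : (n, 3) array
        Raw angular velocity, rad/s, canonical axis order.
    meta : dict
        Free-form provenance.
    """

    sample_rate: float
    time: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    meta: dict = field(default_factory=dict)

    MAX_GYRO_RAD_S = math.radians(2000.0)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    def validate(self) -> None:
        n = self.time.shape[0]
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise IntegrityError("accel/gyro must be (n, 3) arrays matching time")
        if n < 2 * self.sample_rate:
            raise IntegrityError(
                f"recording too short: {n} samples < 2 s at {self.sample_rate} Hz"
            )
        dt = np.diff(self.time)
        step = 1.0 / self.sample_rate
        if np.any(dt <= 0):
            raise IntegrityError("time must be strictly increasing")
        if np.any(np.abs(dt - step) > TIME_STEP_TOL_S):
            raise IntegrityError("non-uniform time step beyond tolerance")
        if not np.all(np.isfinite(self.accel)):
            raise IntegrityError("non-finite accelerometer samples")
        if not np.all(np.isfinite(self.gyro)):
            raise IntegrityError("non-finite gyroscope samples")
        if np.any(np.abs(self.gyro) > self.MAX_GYRO_RAD_S):
            raise IntegrityError("gyroscope magnitude exceeds +/-2000 deg/s range")


@dataclass(frozen=True, order=True)
class PTAnnotation:
    """One reference postural-transition event (video-style annotation)."""

    start: float
    end: float
    direction: str

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class AnnotationSet:
    """Sorted, non-overlapping reference events with a timing resolution."""

    events: list[PTAnnotation]
    resolution: float = 1.0

    def __post_init__(self) -> None:
        self.events = sorted(self.events)
        for ev in self.events:
            if ev.end <= ev.start:
                raise ValidationError(f"event end <= start: {ev}")
            if ev.direction not in DIRECTIONS:
                raise ValidationError(f"unknown direction {ev.direction!r}")
        for a, b in zip(self.events, self.events[1:]):
            if b.start < a.end:
                raise ValidationError(f"overlapping events: {a} / {b}")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


def _interpolate_short_nan_runs(df: pd.DataFrame, sample_rate: float) -> pd.DataFrame:
    """Linearly interpolate NaN runs shorter than ``MAX_NAN_GAP_S``; reject longer."""
    max_run = int(MAX_NAN_GAP_S * sample_rate)
    for col in df.columns:
        isnan = df[col].isna().to_numpy()
        if not isnan.any():
            continue
        # Longest run of consecutive NaNs.
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, isnan.astype(int), 0])))[::2]
        if runs.max() >= max_run:
            raise IntegrityError(
                f"NaN run of {runs.max()} samples in column {col!r} "
                f"exceeds {MAX_NAN_GAP_S} s"
            )
        log.warning(
            "interpolating %d NaN samples in column %s", int(isnan.sum()), col
        )
        df[col] = df[col].interpolate(method="linear", limit_direction="both")
    return df


def read_imu_csv(
    path,
    convention: AxisConvention = IDENTITY_CONVENTION,
    gyro_units: str = "rad/s",
    sample_rate: float | None = None,
) -> ImuRecording:
    """Read an IMU session from CSV (columns t, ax, ay, az, gx, gy, gz).

    ``gyro_units`` may be ``"rad/s"`` or ``"deg/s"``; degrees are converted.
    The sample rate is inferred from the time column unless given.
    """
    if gyro_units not in ("rad/s", "deg/s"):
        raise ValidationError(f"unknown gyro_units {gyro_units!r}")
    df = pd.read_csv(path)
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s) {missing} in {path}")
    df = df[list(IMU_COLUMNS)].astype(float)

    t = df["t"].to_numpy()
    if t.size < 2:
        raise IntegrityError("need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise IntegrityError("duplicated or decreasing timestamps")
    fs = sample_rate if sample_rate is not None else 1.0 / np.median(dt)
    fs = float(np.round(fs))
    df = _interpolate_short_nan_runs(df, fs)

    accel = convention.apply(df[["ax", "ay", "az"]].to_numpy())
    gyro = convention.apply(df[["gx", "gy", "gz"]].to_numpy())
    if gyro_units == "deg/s":
        gyro = np.radians(gyro)
    return ImuRecording(fs, t, accel, gyro, meta={"source": str(path)})


def write_imu_csv(rec: ImuRecording, path) -> None:
    """Write a canonical recording; round-trips through read_imu_csv to 1e-9."""
    df = pd.DataFrame(
        np.column_stack([rec.time, rec.accel, rec.gyro]), columns=IMU_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_imu_hdf5(
    path,
    convention: AxisConvention = IDENTITY_CONVENTION,
    gyro_units: str = "rad/s",
) -> ImuRecording:
    """Read the columnar HDF5 dialect: one dataset per channel + sample_rate attr."""
    with h5py.File(path, "r") as f:
        if "sample_rate" not in f.attrs:
            raise FormatError("missing sample_rate attribute")
        fs = float(f.attrs["sample_rate"])
        cols = {}
        for name in IMU_COLUMNS[1:]:
            if name not in f:
                raise FormatError(f"missing dataset {name!r}")
            cols[name] = np.asarray(f[name], dtype=float)
    n = len(cols["ax"])
    t = np.arange(n) / fs
    accel = convention.apply(np.column_stack([cols["ax"], cols["ay"], cols["az"]]))
    gyro = convention.apply(np.column_stack([cols["gx"], cols["gy"], cols["gz"]]))
    if gyro_units == "deg/s":
        gyro = np.radians(gyro)
    return ImuRecording(fs, t, accel, gyro, meta={"source": str(path)})


def write_imu_hdf5(rec: ImuRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["sample_rate"] = rec.sample_rate
        for i, name in enumerate(("ax", "ay", "az")):
            f.create_dataset(name, data=rec.accel[:, i])
        for i, name in enumerate(("gx", "gy", "gz")):
            f.create_dataset(name, data=rec.gyro[:, i])


def read_annotations(path) -> AnnotationSet:
    """Read a reference annotation CSV with columns start_s, end_s, direction."""
    df = pd.read_csv(path)
    for col in ("start_s", "end_s", "direction"):
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in {path}")
    events = [
        PTAnnotation(float(r.start_s), float(r.end_s), str(r.direction))
        for r in df.itertuples()
    ]
    return AnnotationSet(events)


def write_annotations(ann: AnnotationSet, path) -> None:
    df = pd.DataFrame(
        [(e.start, e.end, e.direction) for e in ann],
        columns=["start_s", "end_s", "direction"],
    )
    df.to_csv(path, index=False, float_format="%.6f")


EVENT_COLUMNS = ("start_s", "end_s", "duration_s", "direction", "class", "delta_dz_m")


def write_events_csv(events: Sequence, path) -> None:
    """Write detected events, one row per event, times in seconds (3 decimals)."""
    rows = []
    for ev in events:
        rows.append(
            (
                f"{ev.start_s:.3f}",
                f"{ev.end_s:.3f}",
                f"{ev.duration:.3f}",
                ev.direction,
                ev.klass,
                f"{ev.delta_dz:.3f}" if np.isfinite(ev.delta_dz) else "nan",
            )
        )
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events_csv(path, sample_rate: float = 128.0) -> list:
    """Load an events CSV back into PTEvent objects (indices from times)."""
    from .detect import PTEvent  # local import to avoid a cycle

    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s) {missing} in {path}")
    out = []
    for r in df.itertuples():
        start = int(round(float(r.start_s) * sample_rate))
        end = int(round(float(r.end_s) * sample_rate))
        out.append(
            PTEvent(
                peak_index=(start + end) // 2,
                start_index=start,
                end_index=end,
                sample_rate=sample_rate,
                delta_dz=float(r.delta_dz_m),
                direction=str(r.direction),
                klass=str(getattr(r, "_5")),  # "class" is a keyword
                peak_value=math.nan,
            )
        )
    return out
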
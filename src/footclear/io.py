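"""Typed containers and readers/writers for IMU, shoe-scan and marker files.

All files are plain CSV (comma delimiter, ``.`` decimal, UTF-8, mandatory
header row).  Internally everything is SI: meters, seconds, m/s^2, rad/s.
Clearances are converted to millimeters only at the output boundary.

The shoe scan is a point list exported from CAD processing of a 3D scan:
a grid of points covering the sole, toe/heel landmarks at the anterior and
posterior extremes, an optional point at the center of a reflective toe
marker, and the IMU fixture (origin plus the three IMU axis directions
expressed in the scan frame).  On read, all point coordinates are stored
relative to the fixture origin, so downstream rigid-body math can treat the
IMU center as the zero of the scan frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, CalibrationError

STANDARD_GRAVITY = 9.80665  # m/s^2, conventional value

# Unit conversion factors into SI
_ACCEL_UNITS = {"m/s^2": 1.0, "m/s2": 1.0, "g": STANDARD_GRAVITY}
_GYRO_UNITS = {"rad/s": 1.0, "deg/s": np.pi / 180.0}


@dataclass(frozen=True)
class ImuDialect:
    """Column naming and unit mapping for an IMU CSV file."""

    time_col: str = "time"
    accel_cols: tuple[str, str, str] = ("ax", "ay", "az")
    gyro_cols: tuple[str, str, str] = ("gx", "gy", "gz")
    accel_unit: str = "m/s^2"
    gyro_unit: str = "rad/s"
    sample_rate: Optional[float] = None  # Hz; inferred from median dt if None


@dataclass
class ImuRecording:
    """Uniformly sampled specific-force / angular-rate recording.

    ``accel`` holds specific force (what the accelerometer measures: body
    acceleration minus gravity, in the sensor frame), ``gyro`` the angular
    rate, both as (n, 3) arrays.
    """

    sample_rate: float
    time: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.time.shape[0]
        if n < 2:
            raise DataError("IMU recording needs at least 2 samples")
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise DataError("accel/gyro must be (n, 3) arrays matching time")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            k = int(np.argmax(dt <= 0))
            raise DataError(f"time must be strictly increasing (sample {k + 1})")
        nominal = 1.0 / self.sample_rate
        if np.max(np.abs(dt - nominal)) >= 0.1 * nominal:
            raise DataError("sampling is not uniform at the stated rate")
        if not (
            np.all(np.isfinite(self.time))
            and np.all(np.isfinite(self.accel))
            and np.all(np.isfinite(self.gyro))
        ):
            raise DataError("IMU recording contains non-finite values")

    def __len__(self) -> int:
        return self.time.shape[0]


@dataclass
class ScanPointCloud:
    """Shoe geometry point list in the scan frame.

    ``points`` are stored relative to the fixture origin (the IMU center),
    i.e. the origin has already been subtracted.  ``sole_indices`` selects
    the grid points covering the bottom surface; ``toe_index``/``heel_index``
    are the anterior/posterior extreme landmarks; ``marker_index`` optionally
    locates the center of a reflective toe marker used for validation.
    """

    points: np.ndarray
    toe_index: int
    heel_index: int
    sole_indices: np.ndarray
    fixture_origin: np.ndarray
    fixture_axes: np.ndarray  # rows = IMU x/y/z directions in the scan frame
    marker_index: Optional[int] = None
    labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.sole_indices = np.asarray(self.sole_indices, dtype=int)
        self.fixture_origin = np.asarray(self.fixture_origin, dtype=float)
        self.fixture_axes = np.asarray(self.fixture_axes, dtype=float)
        n = self.points.shape[0]
        if n < 4:
            raise DataError("point cloud needs at least 4 points")
        idx = [self.toe_index, self.heel_index, *self.sole_indices.tolist()]
        if self.marker_index is not None:
            idx.append(self.marker_index)
        if any(i < 0 or i >= n for i in idx):
            raise DataError("point index out of range")
        if self.sole_indices.size == 0:
            raise DataError("sole_indices must be non-empty")
        if self.sole_indices.size >= 3:
            sole = self.points[self.sole_indices]
            spread = np.linalg.svd(sole - sole.mean(axis=0), compute_uv=False)
            if spread[1] < 1e-12:
                raise DataError("sole points are collinear")
        norms = np.linalg.norm(self.fixture_axes, axis=1)
        if np.any(np.abs(norms - 1.0) > 0.05):
            raise CalibrationError(
                f"fixture axis norms {norms} outside 1 +/- 0.05"
            )
        unit = self.fixture_axes / norms[:, None]
        gram = unit @ unit.T
        off = np.abs(gram - np.eye(3))
        if np.max(off) > 0.1:
            raise CalibrationError("fixture axes are not close to orthogonal")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def sole_dominates(self) -> bool:
        """Heuristic load-time check that no non-sole point can be lowest.

        True when every non-sole point sits strictly above the sole point
        nearest to it in the horizontal (x, y) plane — adequate for the
        moderate foot tilts the method encounters during swing.
        """
        mask = np.zeros(self.n_points, dtype=bool)
        mask[self.sole_indices] = True
        other = self.points[~mask]
        if other.size == 0:
            return True
        sole = self.points[self.sole_indices]
        d2 = (
            (other[:, None, 0] - sole[None, :, 0]) ** 2
            + (other[:, None, 1] - sole[None, :, 1]) ** 2
        )
        nearest = np.argmin(d2, axis=1)
        return bool(np.all(other[:, 2] > sole[nearest, 2]))


@dataclass
class MarkerTrajectory:
    """Optical motion-capture trajectory of one marker in the lab frame."""

    time: np.ndarray
    position: np.ndarray
    gap_mask: np.ndarray  # True = occluded / missing sample

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if np.any(np.diff(self.time) <= 0):
            raise DataError("marker time must be strictly increasing")
        ok = ~self.gap_mask
        if not np.all(np.isfinite(self.position[ok])):
            raise DataError("marker positions must be finite outside gaps")

    def __len__(self) -> int:
        return self.time.shape[0]


def read_imu_recording(path: str | Path, dialect: ImuDialect | None = None) -> ImuRecording:
    """Read an IMU CSV, converting to m/s^2 and rad/s per the dialect."""
    dialect = dialect or ImuDialect()
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # empty file, bad delimiter, ...
        raise FormatError(f"cannot parse IMU CSV {path}: {exc}") from exc
    cols = [dialect.time_col, *dialect.accel_cols, *dialect.gyro_cols]
    for c in cols:
        if c not in df.columns:
            raise FormatError(f"IMU CSV missing column {c!r}")
    if dialect.accel_unit not in _ACCEL_UNITS:
        raise FormatError(f"unknown accelerometer unit {dialect.accel_unit!r}")
    if dialect.gyro_unit not in _GYRO_UNITS:
        raise FormatError(f"unknown gyroscope unit {dialect.gyro_unit!r}")
    time = df[dialect.time_col].to_numpy(dtype=float)
    accel = df[list(dialect.accel_cols)].to_numpy(dtype=float) * _ACCEL_UNITS[dialect.accel_unit]
    gyro = df[list(dialect.gyro_cols)].to_numpy(dtype=float) * _GYRO_UNITS[dialect.gyro_unit]
    if time.size >= 2 and np.any(np.diff(time) <= 0):
        k = int(np.argmax(np.diff(time) <= 0))
        raise DataError(f"non-monotonic time at row {k + 1}")
    rate = dialect.sample_rate
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(time)))
    return ImuRecording(sample_rate=rate, time=time, accel=accel, gyro=gyro)


def write_imu_recording(rec: ImuRecording, path: str | Path) -> None:
    """Write an IMU recording using the default dialect (SI units)."""
    df = pd.DataFrame(
        {
            "time": rec.time,
            "ax": rec.accel[:, 0],
            "ay": rec.accel[:, 1],
            "az": rec.accel[:, 2],
            "gx": rec.gyro[:, 0],
            "gy": rec.gyro[:, 1],
            "gz": rec.gyro[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


_SCAN_ROLES = {"origin", "xaxis", "yaxis", "zaxis", "toe", "heel", "marker", "sole"}
_UNIQUE_ROLES = ("origin", "xaxis", "yaxis", "zaxis", "toe", "heel")


def read_scan_points(path: str | Path, unit_scale: float = 1e-3) -> ScanPointCloud:
    """Read a scan CSV (``label,role,x,y,z``; scanner units mm by default).

    Content-point indices (toe, heel, marker, sole) are assigned in file
    order; coordinates are converted to meters and stored relative to the
    fixture origin.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse scan CSV {path}: {exc}") from exc
    for c in ("label", "role", "x", "y", "z"):
        if c not in df.columns:
            raise FormatError(f"scan CSV missing column {c!r}")
    roles = df["role"].astype(str).str.strip().str.lower()
    bad = set(roles) - _SCAN_ROLES
    if bad:
        raise FormatError(f"unknown scan roles: {sorted(bad)}")
    for role in _UNIQUE_ROLES:
        n = int((roles == role).sum())
        if n == 0:
            raise FormatError(f"scan CSV missing mandatory role {role!r}")
        if n > 1:
            raise FormatError(f"scan CSV has duplicate role {role!r}")
    if int((roles == "marker").sum()) > 1:
        raise FormatError("scan CSV has duplicate role 'marker'")
    if int((roles == "sole").sum()) < 1:
        raise FormatError("scan CSV needs at least one 'sole' row")
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float) * unit_scale
    origin = xyz[roles[roles == "origin"].index[0]]
    # Axis rows store direction vectors: unit_scale must not rescale them.
    axes = np.array(
        [
            df.loc[roles[roles == role].index[0], ["x", "y", "z"]].to_numpy(dtype=float)
            for role in ("xaxis", "yaxis", "zaxis")
        ]
    )
    norms = np.linalg.norm(axes, axis=1)
    if np.any((norms < 0.9) | (norms > 1.1)):
        raise CalibrationError(f"fixture axis norm outside [0.9, 1.1]: {norms}")
    content = roles.isin(["toe", "heel", "marker", "sole"]).to_numpy()
    pts = xyz[content] - origin
    content_roles = roles[content].to_numpy()
    labels = df["label"].astype(str)[content].tolist()
    toe_index = int(np.flatnonzero(content_roles == "toe")[0])
    heel_index = int(np.flatnonzero(content_roles == "heel")[0])
    marker_rows = np.flatnonzero(content_roles == "marker")
    marker_index = int(marker_rows[0]) if marker_rows.size else None
    sole_indices = np.flatnonzero(content_roles == "sole")
    return ScanPointCloud(
        points=pts,
        toe_index=toe_index,
        heel_index=heel_index,
        sole_indices=sole_indices,
        fixture_origin=origin,
        fixture_axes=axes,
        marker_index=marker_index,
        labels=labels,
    )


def write_scan_points(cloud: ScanPointCloud, path: str | Path, unit_scale: float = 1e-3) -> None:
    """Write a scan CSV that round-trips through :func:`read_scan_points`."""
    rows = []
    origin = cloud.fixture_origin
    rows.append(("imu_origin", "origin", *(origin / unit_scale)))
    for name, ax in zip(("xaxis", "yaxis", "zaxis"), cloud.fixture_axes):
        rows.append((f"imu_{name}", name, *ax))
    roles = np.full(cloud.n_points, "sole", dtype=object)
    roles[cloud.toe_index] = "toe"
    roles[cloud.heel_index] = "heel"
    if cloud.marker_index is not None:
        roles[cloud.marker_index] = "marker"
    labels = list(cloud.labels) if len(cloud.labels) == cloud.n_points else [
        f"p{i}" for i in range(cloud.n_points)
    ]
    for i in range(cloud.n_points):
        p = (cloud.points[i] + origin) / unit_scale
        rows.append((labels[i], roles[i], *p))
    df = pd.DataFrame(rows, columns=["label", "role", "x", "y", "z"])
    df.to_csv(path, index=False, float_format="%.12g")


def read_marker_trajectory(path: str | Path) -> MarkerTrajectory:
    """Read a marker CSV (``time,x,y,z``, meters; empty cells mark gaps)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse marker CSV {path}: {exc}") from exc
    for c in ("time", "x", "y", "z"):
        if c not in df.columns:
            raise FormatError(f"marker CSV missing column {c!r}")
    time = df["time"].to_numpy(dtype=float)
    pos = df[["x", "y", "z"]].to_numpy(dtype=float)
    gaps = ~np.all(np.isfinite(pos), axis=1)
    pos = np.where(np.isfinite(pos), pos, 0.0)
    return MarkerTrajectory(time=time, position=pos, gap_mask=gaps)


def write_marker_trajectory(traj: MarkerTrajectory, path: str | Path) -> None:
    pos = traj.position.astype(float).copy()
    pos[traj.gap_mask] = np.nan
    df = pd.DataFrame({"time": traj.time, "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2]})
    df.to_csv(path, index=False, float_format="%.12g")


STRIDE_RESULT_COLUMNS = (
    "stride_id",
    "t_start_s",
    "valid",
    "mfc_mm",
    "k_mfc",
    "i_mfc",
    "k_max_heel",
    "k_max_toe",
)


def write_stride_results(strides, path: str | Path) -> None:
    """Write per-stride clearance results (mFC reported in millimeters).

    Invalid strides keep their row with ``valid`` false and empty numeric
    cells, so downstream counts stay honest.
    """
    if not strides:
        raise DataError("no strides to write")
    rows = []
    for s in strides:
        if s.valid:
            rows.append(
                (
                    s.stride_id,
                    s.t_start,
                    True,
                    s.mfc * 1e3,
                    s.k_mfc,
                    s.i_mfc,
                    s.k_max_heel,
                    s.k_max_toe,
                )
            )
        else:
            rows.append((s.stride_id, s.t_start, False, None, None, None, None, None))
    df = pd.DataFrame(rows, columns=list(STRIDE_RESULT_COLUMNS))
    try:
        df.to_csv(path, index=False, float_format="%.9g")
    except OSError as exc:
        raise FootclearIOError(str(exc)) from exc


class FootclearIOError(FormatError):
    """Unwritable output path."""


def read_stride_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in STRIDE_RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"results CSV missing columns {missing}")
    return df
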
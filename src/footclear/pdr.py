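"""Zero-velocity-update pedestrian dead reckoning for a foot-mounted IMU.

The reconstruction follows the classic strapdown/ZUPT recipe: stance phases
are detected by thresholding the smoothed accelerometer and gyroscope norms,
short spurious stance runs are deleted, strides are segmented between
consecutive stance onsets, and orientation/velocity/position are obtained by
integrating the signals with the velocity pinned to zero during stance.  Two
per-stride height corrections are applied on top: a constant world-frame
acceleration bias estimated from the velocity drift observed over the
stride's terminal stance run, and removal of the residual ("impulsive")
velocity error at heel strike.

Discretisation convention: each gyroscope sample is treated as the
midpoint-rule angular rate of the sampling interval that follows it, i.e.
``R(k+1) = R(k) @ expm([w_k dt])``.  World acceleration is integrated with
the trapezoidal rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.spatial.transform import Rotation

from .errors import DataError, ReconstructionError, SegmentationError
from .io import ImuRecording, STANDARD_GRAVITY

GRAVITY_W = np.array([0.0, 0.0, -STANDARD_GRAVITY])


@dataclass
class ZuptMask:
    """Boolean stance (zero-velocity) flag per sample."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)

    def __len__(self) -> int:
        return self.flags.shape[0]

    def runs(self) -> list[tuple[int, int]]:
        """Maximal True runs as half-open ``[start, end)`` index pairs."""
        f = np.concatenate(([False], self.flags, [False])).astype(int)
        d = np.diff(f)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        return list(zip(starts.tolist(), ends.tolist()))

    @property
    def zupt1(self) -> int:
        """First sample of the first stance run."""
        runs = self.runs()
        if not runs:
            raise ReconstructionError("ZUPT mask has no stance run")
        return runs[0][0]


@dataclass
class StrideSegmentation:
    """Strides as ``(zupt_start, zupt_end, stride_end)`` index triples.

    Stride *n* spans ``[zupt_start_n, zupt_start_{n+1})``; its terminal
    stance run is the initial run of the next stride.
    """

    strides: list[tuple[int, int, int]]

    def __len__(self) -> int:
        return len(self.strides)

    def __iter__(self):
        return iter(self.strides)


@dataclass
class PoseTrajectory:
    """Per-sample IMU orientation (IMU -> world) and world position."""

    rotation: np.ndarray  # (n, 3, 3)
    position: np.ndarray  # (n, 3), meters
    sample_rate: float

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.position = np.asarray(self.position, dtype=float)

    def __len__(self) -> int:
        return self.position.shape[0]


def detect_zupt(
    rec: ImuRecording,
    accel_tol: float = 0.8,
    gyro_tol: float = 0.3,
    smooth_window: int = 5,
) -> ZuptMask:
    """Flag stance samples by thresholding smoothed signal norms.

    A sample is stance when the centered moving average (over
    ``smooth_window`` samples) of the accelerometer norm is within
    ``accel_tol`` of standard gravity and that of the gyroscope norm is
    below ``gyro_tol``.
    """
    if accel_tol <= 0 or gyro_tol <= 0:
        raise DataError("ZUPT tolerances must be positive")
    a_norm = np.linalg.norm(rec.accel, axis=1)
    w_norm = np.linalg.norm(rec.gyro, axis=1)
    a_s = uniform_filter1d(a_norm, size=smooth_window, mode="nearest")
    w_s = uniform_filter1d(w_norm, size=smooth_window, mode="nearest")
    flags = (np.abs(a_s - STANDARD_GRAVITY) < accel_tol) & (w_s < gyro_tol)
    return ZuptMask(flags=flags)


def smooth_zupt(mask: ZuptMask, min_len: int = 15) -> ZuptMask:
    """Delete stance runs shorter than ``min_len`` samples (idempotent)."""
    flags = mask.flags.copy()
    for start, end in mask.runs():
        if end - start < min_len:
            flags[start:end] = False
    return ZuptMask(flags=flags)


def segment_strides(mask: ZuptMask) -> StrideSegmentation:
    """One stride per consecutive pair of stance runs.

    Samples after the start of the last run do not form a stride (there is
    no terminating stance) and are discarded from striding.
    """
    runs = mask.runs()
    if len(runs) < 2:
        raise SegmentationError(
            f"need at least 2 stance runs to segment strides, found {len(runs)}"
        )
    strides = []
    for (s0, e0), (s1, _e1) in zip(runs[:-1], runs[1:]):
        strides.append((s0, e0, s1))
    return StrideSegmentation(strides=strides)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit direction ``a`` onto ``b``."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    axis = np.cross(a, b)
    s = np.linalg.norm(axis)
    c = float(np.dot(a, b))
    if s < 1e-15:
        if c > 0:
            return np.eye(3)
        # Antiparallel: rotate pi about any axis orthogonal to a.
        ortho = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            ortho = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, ortho)
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    angle = np.arctan2(s, c)
    return Rotation.from_rotvec(axis / s * angle).as_matrix()


def reconstruct_pose(
    rec: ImuRecording,
    mask: ZuptMask,
    tilt_gain: float = 0.02,
    bias_correction: bool = True,
    level_height: bool = True,
) -> PoseTrajectory:
    """Drift-corrected strapdown integration anchored on stance runs.

    Steps: (i) initial orientation from the mean specific force over the
    first stance run (tilt only, heading zero); (ii) orientation propagated
    by rotation-vector integration, with stance-phase tilt relaxed toward
    the gravity-measured tilt by a first-order complementary gain;
    (iii) world acceleration integrated to velocity (trapezoid), reset to
    zero over every stance run; (iv) per stride, a constant world-frame
    acceleration bias estimated by least squares from the velocity ramp
    observed over the stride's terminal stance run and removed; (v) any
    residual mean velocity over that run removed as a step from heel strike
    onward; (vi) position by trapezoidal integration of corrected velocity.

    ``bias_correction=False`` disables steps (iv)-(v), exposing the
    uncorrected trajectory for comparison.  ``level_height`` re-anchors the
    zero height at every stance run (level-floor convention) by removing
    any residual stance-to-stance height increment as a continuous
    per-stride ramp.
    """
    n = len(rec)
    if len(mask) != n:
        raise DataError("mask and recording lengths differ")
    runs = mask.runs()
    if not runs:
        raise ReconstructionError("cannot reconstruct without a stance run")
    dt = 1.0 / rec.sample_rate
    f = rec.accel
    w = rec.gyro

    # (i) initial orientation: align mean stance specific force with +z.
    s0, e0 = runs[0]
    f0 = f[s0:e0].mean(axis=0)
    if np.linalg.norm(f0) < 1e-6:
        raise ReconstructionError("stance specific force is degenerate")
    R = np.empty((n, 3, 3))
    R[s0] = _rotation_between(f0, np.array([0.0, 0.0, 1.0]))

    z_hat = np.array([0.0, 0.0, 1.0])

    def relax_tilt(Rk: np.ndarray, fk: np.ndarray) -> np.ndarray:
        norm = np.linalg.norm(fk)
        if norm < 1e-9:
            return Rk
        g_dir = Rk @ (fk / norm)
        axis = np.cross(g_dir, z_hat)
        s = np.linalg.norm(axis)
        c = float(np.dot(g_dir, z_hat))
        if s < 1e-15:
            return Rk
        angle = np.arctan2(s, c)
        corr = Rotation.from_rotvec(axis / s * (tilt_gain * angle)).as_matrix()
        return corr @ Rk

    # (ii) propagate orientation forward from the first stance onset (and
    # backward over any leading samples).
    for k in range(s0, n - 1):
        Rk = R[k]
        if mask.flags[k]:
            Rk = relax_tilt(Rk, f[k])
            R[k] = Rk
        R[k + 1] = Rk @ Rotation.from_rotvec(w[k] * dt).as_matrix()
    if mask.flags[n - 1]:
        R[n - 1] = relax_tilt(R[n - 1], f[n - 1])
    for k in range(s0 - 1, -1, -1):
        R[k] = R[k + 1] @ Rotation.from_rotvec(-w[k] * dt).as_matrix()

    # (iii) world acceleration and stance-anchored velocity.
    a_w = np.einsum("kij,kj->ki", R, f) + GRAVITY_W
    v = np.zeros((n, 3))
    incr = 0.5 * dt * (a_w[:-1] + a_w[1:])  # trapezoid increments
    stance = mask.flags

    def integrate(first: int, last: int) -> None:
        """Velocity from trapezoid increments over (first, last]; v[first]=0."""
        if last <= first:
            return
        v[first + 1 : last + 1] = np.cumsum(incr[first:last], axis=0)

    # Integrate each span anchored at the last sample of a stance run,
    # running through the *end* of the following stance run so that the
    # velocity drift accumulated over that terminal run stays observable
    # for the bias estimate below.  The leading span (before the first
    # run) has no anchor and is left at rest.
    for i, (_s_i, e_i) in enumerate(runs):
        nxt_end = runs[i + 1][1] if i + 1 < len(runs) else n
        integrate(e_i - 1, nxt_end - 1)

    # (iv)-(v) per-stride bias ramp and heel-strike impulse removal.
    if bias_correction and len(runs) >= 2:
        t = rec.time
        for i in range(len(runs) - 1):
            _s_a, e_a = runs[i]
            s_b, e_b = runs[i + 1]
            k0 = e_a - 1  # integration anchor of this stride
            sl = slice(k0 + 1, e_b)
            tau = t[sl] - t[k0]
            tau_T = t[s_b:e_b] - t[k0]
            v_T = v[s_b:e_b]
            denom = float(np.sum(tau_T**2))
            if denom > 0:
                b = (tau_T @ v_T) / denom  # least-squares constant accel bias
                v[sl] -= np.outer(tau, b)
            resid = v[s_b:e_b].mean(axis=0)
            v[s_b:e_b] -= resid  # impulsive velocity error at heel strike

    # Stance-phase zero-velocity reset (exact, after all corrections).
    for s_i, e_i in runs:
        v[s_i:e_i] = 0.0

    # (vi) position by trapezoid of corrected velocity; constant during
    # stance by construction (v = 0 there), continuous across strides.
    p = np.zeros((n, 3))
    p[1:] = np.cumsum(0.5 * dt * (v[:-1] + v[1:]), axis=0)

    # Height convention: zero height is (re-)anchored at every stance run —
    # walking surfaces in scope are level, so any residual stance-to-stance
    # height increment is integration drift.  It is removed as a continuous
    # per-stride ramp (no reset jumps), leaving x/y untouched.
    if level_height and len(runs) >= 2:
        t = rec.time
        z_ref = p[runs[0][0] : runs[0][1], 2].mean()
        corr = np.zeros(n)
        c_prev = 0.0
        for i in range(len(runs) - 1):
            _s_a, e_a = runs[i]
            s_b, e_b = runs[i + 1]
            c_next = p[s_b:e_b, 2].mean() - z_ref
            span = t[s_b] - t[e_a - 1]
            sl = slice(e_a, s_b)
            corr[sl] = c_prev + (c_next - c_prev) * (t[sl] - t[e_a - 1]) / span
            corr[s_b:e_b] = c_next
            c_prev = c_next
        corr[runs[-1][1] :] = c_prev
        p[:, 2] -= corr

    return PoseTrajectory(rotation=R, position=p, sample_rate=rec.sample_rate)
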
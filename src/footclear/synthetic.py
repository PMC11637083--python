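"""Synthetic gait: ground-truth foot poses, IMU signal synthesis, and an
analytic clearance oracle.

The generator emulates level over-ground walking of an instrumented shoe:
flat, truly stationary stance phases alternating with swing phases whose
forward displacement follows a raised-cosine *velocity* profile and whose
sagittal rotation runs from early-swing plantarflexion to late-swing
dorsiflexion.  With full late-swing dorsiflexion the toe-height path is
M-shaped (two maxima per stride); scaling the dorsiflexion down with
``foot_drop_factor`` collapses it to a single peak, mimicking foot drop.
An optional swing-phase roll sinusoid emulates inversion, pushing the
instantaneous lowest point to the lateral sole edge.  All profiles are
built from quintic smoothsteps and are therefore twice continuously
differentiable, so synthesized accelerations are free of impulsive
artifacts at the stance/swing boundaries.

What this emulates — and what it does not: rigid-body shoe kinematics with
ideal sensor noise (white Gaussian, constant accelerometer bias).  It does
not model shoe deformation, ground contact dynamics, sensor scale factors
or mounting compliance; the reconstruction method itself assumes rigidity,
so the simulator matches the method's assumptions by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DataError
from .io import ImuRecording, ScanPointCloud, MarkerTrajectory, STANDARD_GRAVITY


def smoothstep(u: np.ndarray) -> np.ndarray:
    """Quintic smoothstep: 0 -> 1 over [0, 1] with zero first and second
    derivatives at both ends (C2 when used piecewise)."""
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


def _window(tau, up0, up1, down0, down1):
    """C2 window rising over [up0, up1] and falling over [down0, down1]."""
    return smoothstep((tau - up0) / (up1 - up0)) - smoothstep(
        (tau - down0) / (down1 - down0)
    )


@dataclass
class GaitParams:
    """Parameters of the synthetic walking bout.

    Defaults describe an unimpaired adult walking at a comfortable pace:
    1.1 s stride time, 60% stance, 0.65 m steps, ~9 cm swing foot lift,
    14 deg early-swing plantarflexion and 14 deg late-swing dorsiflexion.
    """

    seed: int
    stride_time: float = 1.1  # s
    stance_fraction: float = 0.6
    step_length: float = 0.65  # m
    swing_apex_height: float = 0.09  # m, vertical IMU excursion
    pitch_plantarflex_deg: float = 14.0
    pitch_dorsiflex_deg: float = 14.0
    roll_amplitude_deg: float = 0.0  # inversion amplitude
    foot_drop_factor: float = 1.0  # 1 = full late-swing dorsiflexion
    n_strides: int = 10
    sample_rate: float = 128.0  # Hz
    accel_noise_sd: float = 0.0  # m/s^2
    gyro_noise_sd: float = 0.0  # rad/s
    accel_bias: tuple[float, float, float] = (0.0, 0.0, 0.0)  # sensor frame

    def __post_init__(self) -> None:
        if not (0.3 < self.stance_fraction < 0.8):
            raise DataError("stance_fraction must lie in (0.3, 0.8)")
        if not (0.0 <= self.foot_drop_factor <= 1.0):
            raise DataError("foot_drop_factor must lie in [0, 1]")
        for name in ("stride_time", "step_length", "swing_apex_height", "sample_rate"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be positive")
        if self.n_strides < 1:
            raise DataError("n_strides must be >= 1")


@dataclass
class GroundTruth:
    """Exact poses, stance schedule, and the analytic pose function."""

    rotation: np.ndarray  # (n, 3, 3), IMU -> world
    position: np.ndarray  # (n, 3), world, IMU origin
    time: np.ndarray
    sample_rate: float
    zupt_schedule: list[tuple[int, int]]  # stance runs, half-open
    stance_height: float  # world z of the IMU during flat stance
    params: GaitParams
    pose_fn: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]] = field(repr=False)

    def stance_mask(self) -> np.ndarray:
        m = np.zeros(len(self.time), dtype=bool)
        for s, e in self.zupt_schedule:
            m[s:e] = True
        return m


def make_shoe_cloud(
    length: float = 0.28,
    width: float = 0.10,
    rocker_rise: float = 0.008,
    grid_spacing: float = 0.012,
) -> ScanPointCloud:
    """Synthetic shoe scan: a sole grid over a stadium outline with a
    smooth quartic rocker rising to ``rocker_rise`` at the tips, toe/heel
    landmarks at the anterior/posterior extremes, a dorsal toe-marker
    point, and an IMU fixture on the mid-dorsum aligned with the scan
    axes.

    This is a synthetic stand-in for a CAD-processed 3D scan of a real
    shoe; it satisfies the sole-dominance condition (no dorsal point can
    ever be the lowest during moderate tilts).
    """
    if not (length > width > 0):
        raise DataError("need length > width > 0")
    if grid_spacing >= width / 3:
        raise DataError("grid_spacing must be < width / 3")
    half_w = width / 2.0

    def outline_halfwidth(x: np.ndarray) -> np.ndarray:
        hw = np.full_like(x, half_w)
        heel = x < half_w
        toe = x > length - half_w
        hw[heel] = np.sqrt(np.maximum(half_w**2 - (half_w - x[heel]) ** 2, 0.0))
        hw[toe] = np.sqrt(np.maximum(half_w**2 - (x[toe] - (length - half_w)) ** 2, 0.0))
        return hw

    def rocker(x: np.ndarray) -> np.ndarray:
        return rocker_rise * ((x - length / 2) / (length / 2)) ** 4

    # grids symmetric about the sole's midlines, so the flat stance support
    # plane is exactly horizontal by symmetry
    xs = np.linspace(0.0, length, int(round(length / grid_spacing)) + 1)
    m_y = int(np.floor(width / grid_spacing)) + 1
    ys_full = grid_spacing * (np.arange(m_y) - (m_y - 1) / 2.0)
    pts = []
    for x in xs:
        hw = float(outline_halfwidth(np.array([x]))[0])
        ys = ys_full[np.abs(ys_full) <= hw + 1e-12]
        if ys.size == 0:
            ys = np.array([0.0])
        z = float(rocker(np.array([x]))[0])
        for y in ys:
            pts.append((x, y, z))
    sole = np.asarray(pts)
    # tip points so toe-to-heel distance equals the nominal length exactly
    landmark_z = 0.02
    toe_pt = np.array([length, 0.0, landmark_z])
    heel_pt = np.array([0.0, 0.0, landmark_z])
    marker_pt = np.array([length - 0.015, 0.0, 0.05])
    origin = np.array([0.4 * length, 0.0, 0.06])  # mid-dorsum IMU center
    points = np.vstack([toe_pt, heel_pt, marker_pt, sole])
    cloud = ScanPointCloud(
        points=points - origin,
        toe_index=0,
        heel_index=1,
        marker_index=2,
        sole_indices=np.arange(3, points.shape[0]),
        fixture_origin=origin,
        fixture_axes=np.eye(3),
        labels=["toe", "heel", "marker"] + [f"sole{i}" for i in range(sole.shape[0])],
    )
    return cloud


# Swing profile breakpoints (fractions of swing time).  The vertical bump
# rises to the apex by 0.3, descends to a mid-level shelf over [0.45, 0.8]
# on the same smoothstep that releases the early-swing plantarflexion (so
# the toe descends monotonically when there is no late dorsiflexion), and
# drops to the floor at heel strike.  Late dorsiflexion over [0.75, 0.92]
# is what carves the M into the toe path; scaling it away with
# foot_drop_factor leaves a single-peaked path.
_Z_SHELF = 0.4


def _swing_profiles(tau: np.ndarray, params: GaitParams):
    """(forward_fraction, z_bump_fraction, pitch_rad, roll_rad) at tau."""
    tau = np.asarray(tau, dtype=float)
    fwd = tau - np.sin(2 * np.pi * tau) / (2 * np.pi)  # raised-cosine velocity
    release = smoothstep((tau - 0.45) / 0.35)
    z = (
        smoothstep(tau / 0.3)
        - (1.0 - _Z_SHELF) * release
        - _Z_SHELF * smoothstep((tau - 0.85) / 0.15)
    )
    # With full dorsiflexion control (foot_drop_factor 1) the early-swing
    # plantarflexion is fully released by late swing; with foot drop part
    # of it persists — the forefoot hangs low, as in the clinical gait.
    residual = 0.5 * (1.0 - params.foot_drop_factor)
    plantar = smoothstep(tau / 0.2) - (1.0 - residual) * release
    dorsi = _window(tau, 0.75, 0.92, 0.92, 1.0)
    pitch = np.radians(params.pitch_plantarflex_deg) * plantar - (
        params.foot_drop_factor * np.radians(params.pitch_dorsiflex_deg) * dorsi
    )
    # positive roll drops the lateral (negative-y, right-foot) sole edge
    roll = np.radians(params.roll_amplitude_deg) * _window(tau, 0.55, 0.8, 0.85, 1.0)
    return fwd, z, pitch, roll


def simulate_foot_poses(params: GaitParams, cloud: Optional[ScanPointCloud] = None) -> GroundTruth:
    """Ground-truth IMU poses for a walking bout.

    Stance: constant pose, foot flat, sole support plane at height zero
    (the stance IMU height is chosen from the cloud, or from a default
    sole drop of 6 cm when no cloud is given).  Swing: C2 forward/vertical
    displacement and pitch/roll profiles as described in the module
    docstring.  The bout comprises ``n_strides`` strides plus a terminal
    stance period so the last stride is closed by a stance run.
    """
    if cloud is not None:
        z0 = -float(np.min(cloud.points[cloud.sole_indices, 2]))
    else:
        z0 = 0.06
    T = params.stride_time
    st = params.stance_fraction * T
    sw = T - st
    fs = params.sample_rate

    def pose_fn(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        stride_idx = np.minimum(np.floor(t / T).astype(int), params.n_strides)
        t_local = t - stride_idx * T
        in_swing = (t_local >= st) & (stride_idx < params.n_strides)
        tau = np.zeros_like(t)
        tau[in_swing] = (t_local[in_swing] - st) / sw
        fwd, zb, pitch, roll = _swing_profiles(tau, params)
        fwd = np.where(in_swing, fwd, 0.0)
        zb = np.where(in_swing, zb, 0.0)
        pitch = np.where(in_swing, pitch, 0.0)
        roll = np.where(in_swing, roll, 0.0)
        pos = np.column_stack(
            [
                stride_idx * params.step_length + params.step_length * fwd,
                np.zeros_like(t),
                z0 + params.swing_apex_height * zb,
            ]
        )
        rot = (
            Rotation.from_euler("y", pitch[:, None])
            * Rotation.from_euler("x", roll[:, None])
        ).as_matrix()
        return rot, pos

    total_t = params.n_strides * T + st
    n = int(round(total_t * fs)) + 1
    time = np.arange(n) / fs
    rot, pos = pose_fn(time)
    schedule = []
    for i in range(params.n_strides + 1):
        a = int(np.ceil(i * T * fs - 1e-9))
        b = int(np.floor((i * T + st) * fs + 1e-9)) + 1
        schedule.append((a, min(b, n)))
    return GroundTruth(
        rotation=rot,
        position=pos,
        time=time,
        sample_rate=fs,
        zupt_schedule=schedule,
        stance_height=z0,
        params=params,
        pose_fn=pose_fn,
    )


def synthesize_imu(truth: GroundTruth, params: GaitParams) -> ImuRecording:
    """IMU signals from ground-truth poses.

    World acceleration comes from central second differences of position;
    specific force is ``R(k)^T (a_world - g)``; the gyro sample at k is the
    rotation vector of ``R(k)^T R(k+1)`` times the sample rate (the average
    rate over the following interval).  Sharing the discretisation with the
    reconstruction isolates algorithmic error from discretisation error.
    Gaussian noise and a constant sensor-frame accelerometer bias are added
    from a generator seeded by ``params.seed``; identical seeds give
    bit-identical recordings.
    """
    p = truth.position
    R = truth.rotation
    n = p.shape[0]
    if n < 3:
        raise DataError("need at least 3 samples to synthesize an IMU signal")
    fs = truth.sample_rate
    a_w = np.zeros_like(p)
    a_w[1:-1] = (p[2:] - 2 * p[1:-1] + p[:-2]) * fs**2
    a_w[0] = a_w[1]
    a_w[-1] = a_w[-2]
    g = np.array([0.0, 0.0, -STANDARD_GRAVITY])
    f = np.einsum("kji,kj->ki", R, a_w - g)  # R^T (a - g)
    gyro = np.zeros_like(p)
    rel = np.einsum("kji,kjl->kil", R[:-1], R[1:])  # R_k^T R_{k+1}
    gyro[:-1] = Rotation.from_matrix(rel).as_rotvec() * fs
    gyro[-1] = gyro[-2]
    rng = np.random.default_rng(params.seed)
    accel = f + np.asarray(params.accel_bias, dtype=float)
    if params.accel_noise_sd > 0:
        accel = accel + rng.normal(0.0, params.accel_noise_sd, size=f.shape)
    if params.gyro_noise_sd > 0:
        gyro = gyro + rng.normal(0.0, params.gyro_noise_sd, size=gyro.shape)
    return ImuRecording(sample_rate=fs, time=truth.time, accel=accel, gyro=gyro.copy())


@dataclass
class OracleStride:
    stride_id: int
    k_start: int
    k_end: int
    k_max_heel: int
    k_max_toe: int
    valid: bool
    mfc: Optional[float]
    k_mfc: Optional[int]
    i_mfc: Optional[int]
    lp: np.ndarray  # lowest-point trace over the stride's samples


def oracle_clearance(truth: GroundTruth, cloud: ScanPointCloud) -> list[OracleStride]:
    """Brute-force clearance evaluation on the exact poses.

    Transforms the *entire* cloud with the true poses (no integration, no
    flat-foot correction, no floor estimation — stance is exactly flat at
    height zero by construction) and evaluates the lowest-point trace, the
    forward-swing window, and the minimum clearance per stride, taking
    minima/maxima over all points with first-index tie-breaks.
    """
    world = np.einsum("kij,nj->kni", truth.rotation, cloud.points) + truth.position[:, None, :]
    z = world[..., 2]
    lp_all = z.min(axis=1)
    lp_idx = z.argmin(axis=1)
    stance = truth.stance_mask()
    out = []
    starts = [s for s, _e in truth.zupt_schedule]
    for i in range(len(starts) - 1):
        k0, k1 = starts[i], starts[i + 1]
        heel = z[k0:k1, cloud.heel_index]
        toe = z[k0:k1, cloud.toe_index]
        k_heel = k0 + int(np.argmax(heel))
        k_toe = k0 + int(np.argmax(toe))
        valid = bool(k_heel < k_toe and not stance[k_heel] and not stance[k_toe])
        mfc = k_mfc = i_mfc = None
        if valid:
            seg = lp_all[k_heel : k_toe + 1]
            k_mfc = k_heel + int(np.argmin(seg))
            mfc = float(lp_all[k_mfc])
            i_mfc = int(lp_idx[k_mfc])
        out.append(
            OracleStride(
                stride_id=i,
                k_start=k0,
                k_end=k1,
                k_max_heel=k_heel,
                k_max_toe=k_toe,
                valid=valid,
                mfc=mfc,
                k_mfc=k_mfc,
                i_mfc=i_mfc,
                lp=lp_all[k0:k1].copy(),
            )
        )
    return out


def reference_marker_trajectory(
    truth: GroundTruth,
    cloud: ScanPointCloud,
    rate: float = 200.0,
    noise_sd: float = 0.0,
    height_offset: float = 0.0,
    seed: int = 0,
) -> MarkerTrajectory:
    """Marker trajectory as an optical reference system would record it.

    Evaluates the analytic pose at ``rate`` Hz, transforms the cloud's
    marker point, and optionally adds measurement noise and a constant
    height offset.  Serves as the synthetic stand-in for motion capture.
    """
    if cloud.marker_index is None:
        raise DataError("cloud has no marker point")
    t_end = truth.time[-1]
    # cover the full IMU span (the pose function holds the terminal stance)
    t = np.arange(int(np.ceil(t_end * rate)) + 1) / rate
    rot, pos = truth.pose_fn(t)
    marker = np.einsum("kij,j->ki", rot, cloud.points[cloud.marker_index]) + pos
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        marker = marker + rng.normal(0.0, noise_sd, size=marker.shape)
    marker[:, 2] += height_offset
    return MarkerTrajectory(time=t, position=marker, gap_mask=np.zeros(t.size, bool))


SCENARIOS = ("typical", "foot_drop", "inversion", "toe_drag")


def scenario_params(name: str, seed: int, n_strides: int = 20, **overrides) -> GaitParams:
    """Parameter pack mirroring the qualitative walking styles studied:
    typical gait (M-shaped toe path), foot drop (no late-swing
    dorsiflexion, single-peaked toe path), inversion (lateral sole edge
    lowest in late swing), and toe drag (lowered swing, negative
    clearance)."""
    base = dict(seed=seed, n_strides=n_strides)
    packs = {
        "typical": {},
        "foot_drop": {"foot_drop_factor": 0.0},
        "inversion": {"roll_amplitude_deg": 8.0, "foot_drop_factor": 0.8},
        "toe_drag": {"swing_apex_height": 0.025},
    }
    if name not in packs:
        raise DataError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    base.update(packs[name])
    base.update(overrides)
    return GaitParams(**base)


def simulate_agreement_differences(
    seed: int,
    n_participants: int = 3,
    n_strides: int = 50,
    n_keypoints: int = 3,
    bias: float = -0.05,
    sd_participant: float = 2.0,
    sd_stride: float = 2.0,
    sd_residual: float = 3.0,
    exact_moments: bool = True,
):
    """Nested method-difference data for limits-of-agreement recovery.

    Draws participant, stride-within-participant, and residual effects from
    normal distributions.  With ``exact_moments`` (default) each effect
    vector is standardised to zero mean and exactly the requested SD, so
    the realised variance components equal their nominal values; with only
    a handful of participants this is what makes estimator recovery
    testable against the closed-form limits, rather than a roll of the
    participant-sampling dice.  Returns ``(differences, participant_ids,
    stride_ids)`` with differences in the same units as the SDs.
    """
    rng = np.random.default_rng(seed)

    def draw(n: int, sd: float) -> np.ndarray:
        x = rng.normal(0.0, 1.0, n)
        if exact_moments and n > 1 and sd > 0:
            x = (x - x.mean()) / x.std(ddof=1)
        return x * sd

    u = draw(n_participants, sd_participant)
    w = draw(n_participants * n_strides, sd_stride).reshape(n_participants, n_strides)
    e = draw(n_participants * n_strides * n_keypoints, sd_residual).reshape(
        n_participants, n_strides, n_keypoints
    )
    d, pid, sid = [], [], []
    for i in range(n_participants):
        for j in range(n_strides):
            for k in range(n_keypoints):
                d.append(bias + u[i] + w[i, j] + e[i, j, k])
                pid.append(f"P{i}")
                sid.append(f"P{i}-S{j}")
    return np.asarray(d), np.asarray(pid), np.asarray(sid)
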
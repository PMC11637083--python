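"""Scan-to-world frame fusion: fixture calibration, flat-foot correction,
rigid point-cloud propagation, and floor-height estimation.

The world position of scan point *i* at sample *k* is

    p_world_i(k) = p_imu(k) + R(k) (R_star R_s2i) p_scan_i  -  (0, 0, offset)

where ``R_s2i`` maps scan-frame vectors into IMU coordinates (built from the
fixture axes), ``R_star`` is the constant per-bout flat-foot correction
expressed in the IMU frame at the first stance sample, and ``offset`` is the
trial-level floor height derived from stance-phase lowest points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import CalibrationError, DataError, PlaneFitError
from .io import ScanPointCloud
from .pdr import PoseTrajectory, _rotation_between


@dataclass
class SupportPlane:
    """Plane flush against the bottom of a point set: {p : n . p = offset}."""

    normal: np.ndarray  # unit, upward (n_z > 0)
    offset: float

    def height_above(self, points: np.ndarray) -> np.ndarray:
        return points @ self.normal - self.offset

    @property
    def tilt_deg(self) -> float:
        """Angle between the plane normal and vertical, degrees."""
        return float(np.degrees(np.arccos(np.clip(self.normal[2], -1.0, 1.0))))


@dataclass
class FrameCalibration:
    """Constant per-bout rotations and the trial-level vertical offset."""

    r_scan_to_imu: np.ndarray
    r_star: np.ndarray
    floor_offset: float = 0.0

    def __post_init__(self) -> None:
        for name, r in (("r_scan_to_imu", self.r_scan_to_imu), ("r_star", self.r_star)):
            r = np.asarray(r, dtype=float)
            if abs(np.linalg.det(r) - 1.0) > 1e-9 or np.linalg.norm(r.T @ r - np.eye(3)) > 1e-9:
                raise CalibrationError(f"{name} is not a proper rotation")
        angle = np.linalg.norm(Rotation.from_matrix(self.r_star).as_rotvec())
        if np.degrees(angle) > 15.0 + 1e-9:
            raise CalibrationError(
                f"flat-foot correction of {np.degrees(angle):.1f} deg exceeds 15 deg"
            )


def fixture_rotation(cloud: ScanPointCloud) -> np.ndarray:
    """Nearest proper rotation mapping scan-frame vectors into IMU axes.

    The fixture axes are the IMU basis directions expressed in the scan
    frame; stacking them as rows gives an approximately orthogonal matrix
    whose polar factor (orthogonal Procrustes projection) is returned.
    """
    axes = np.asarray(cloud.fixture_axes, dtype=float)
    norms = np.linalg.norm(axes, axis=1)
    m = axes / norms[:, None]
    if abs(np.linalg.det(m)) < 0.5:
        raise CalibrationError("fixture axes are nearly coplanar/parallel")
    u, _s, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    r = u @ np.diag([1.0, 1.0, d]) @ vt
    return r


def fit_support_plane(
    points: np.ndarray, contact_tol: float = 3e-3, max_iter: int = 20
) -> SupportPlane:
    """Fit the plane flush against the bottom of a point set.

    Iterative scheme: seed the contact set with points within ``contact_tol``
    of the minimum height, fit a least-squares plane through it (total least
    squares via SVD), re-select points within ``contact_tol`` of that plane
    along its normal, and repeat to a fixed point.  The plane is finally
    translated along its normal so that no point lies below it.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 3:
        raise PlaneFitError("need at least 3 points for a support plane")

    def ls_plane(sub: np.ndarray) -> np.ndarray:
        c = sub.mean(axis=0)
        _u, s, vt = np.linalg.svd(sub - c)
        if sub.shape[0] < 3 or s[1] < 1e-12:
            raise PlaneFitError("contact set is collinear")
        normal = vt[2]
        if normal[2] < 0:
            normal = -normal
        if normal[2] < 1e-6:
            raise PlaneFitError("support plane is vertical")
        return normal

    contact = points[:, 2] <= points[:, 2].min() + contact_tol
    normal = None
    for _ in range(max_iter):
        normal = ls_plane(points[contact])
        d = points @ normal
        # The LS plane passes through the contact centroid, so signed
        # distance along the normal is d minus that centroid's projection.
        new_contact = np.abs(d - d[contact].mean()) <= contact_tol
        if np.array_equal(new_contact, contact):
            contact = new_contact
            break
        contact = new_contact
    normal = ls_plane(points[contact])
    offset = float(np.min(points @ normal))
    return SupportPlane(normal=normal, offset=offset)


def compute_flat_correction(
    cloud: ScanPointCloud,
    r_scan_to_imu: np.ndarray,
    pose_at_zupt1: np.ndarray,
    contact_tol: float = 3e-3,
    max_iter: int = 20,
) -> np.ndarray:
    """Flat-foot correction R*, expressed in the IMU frame at ZUPT_1.

    The sole's support plane is fit to the world-frame cloud at the first
    stance sample; the minimal world rotation taking its normal to vertical
    is conjugated into the IMU frame, giving a constant rotation that can be
    applied at every sample between the IMU pose and the scan-to-IMU
    rotation.
    """
    r_wi = np.asarray(pose_at_zupt1, dtype=float)
    z_hat = np.array([0.0, 0.0, 1.0])
    sole = cloud.points[cloud.sole_indices]
    # The support-plane contact set can shift once the cloud is rotated
    # (curved soles), so the minimal leveling rotation is iterated to a
    # fixed point; each pass composes another small correction.
    r_flat = np.eye(3)
    for _ in range(10):
        world_pts = sole @ (r_flat @ r_wi @ r_scan_to_imu).T
        plane = fit_support_plane(world_pts, contact_tol=contact_tol, max_iter=max_iter)
        if plane.tilt_deg <= 0.01:
            break
        r_flat = _rotation_between(plane.normal, z_hat) @ r_flat
    r_star = r_wi.T @ r_flat @ r_wi
    # Post-condition: the corrected cloud's support plane is vertical.
    corrected = sole @ (r_wi @ r_star @ r_scan_to_imu).T
    check = fit_support_plane(corrected, contact_tol=contact_tol, max_iter=max_iter)
    if check.tilt_deg > 0.05:
        raise CalibrationError(
            f"flat correction left {check.tilt_deg:.3f} deg of residual tilt"
        )
    return r_star


def transform_cloud(
    pose: PoseTrajectory, k: int, calib: FrameCalibration, cloud: ScanPointCloud
) -> np.ndarray:
    """World positions of every cloud point at sample ``k``."""
    n = len(pose)
    if not (0 <= k < n):
        raise IndexError(f"sample {k} out of range [0, {n})")
    r_total = pose.rotation[k] @ calib.r_star @ calib.r_scan_to_imu
    out = pose.position[k] + cloud.points @ r_total.T
    out[:, 2] -= calib.floor_offset
    return out


def transform_cloud_all(
    pose: PoseTrajectory, calib: FrameCalibration, cloud: ScanPointCloud
) -> np.ndarray:
    """World positions of the whole cloud at every sample, (n, N, 3)."""
    r_const = calib.r_star @ calib.r_scan_to_imu
    rotated = np.einsum("kij,nj->kni", pose.rotation @ r_const, cloud.points)
    out = rotated + pose.position[:, None, :]
    out[..., 2] -= calib.floor_offset
    return out


def compute_floor_offset(lp_by_zupt: list[np.ndarray]) -> float:
    """Trial-level vertical offset: mean over strides of the median
    stance-phase lowest-point height."""
    if not lp_by_zupt:
        raise DataError("no stance lowest-point sequences given")
    medians = []
    for lp in lp_by_zupt:
        lp = np.asarray(lp, dtype=float)
        if lp.size == 0:
            raise DataError("a stride has no stance samples")
        medians.append(np.median(lp))
    return float(np.mean(medians))
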
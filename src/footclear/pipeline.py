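"""End-to-end bout analysis: detect -> smooth -> segment -> reconstruct ->
calibrate -> clearance, plus the validation pipeline against a reference
marker trajectory."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import clearance as clr
from . import fusion, pdr, validation
from .config import RunConfig
from .io import ImuRecording, MarkerTrajectory, ScanPointCloud

logger = logging.getLogger(__name__)


@dataclass
class BoutResult:
    """Everything the clearance pipeline computes for one walking bout."""

    mask: pdr.ZuptMask
    segmentation: pdr.StrideSegmentation
    pose: pdr.PoseTrajectory
    calibration: fusion.FrameCalibration
    lp: np.ndarray
    lp_index: np.ndarray
    heel_z: np.ndarray
    toe_z: np.ndarray
    marker_z: Optional[np.ndarray]
    strides: list[clr.StrideClearance]
    windows: list[clr.ForwardSwingWindow]
    late_swing_locations: np.ndarray
    n_deleted_runs: int = 0

    @property
    def valid_strides(self) -> list[clr.StrideClearance]:
        return [s for s in self.strides if s.valid]


def analyze_bout(
    rec: ImuRecording, cloud: ScanPointCloud, config: Optional[RunConfig] = None
) -> BoutResult:
    """Run the full clearance pipeline on one IMU recording + shoe scan."""
    cfg = config or RunConfig()
    raw = pdr.detect_zupt(
        rec,
        accel_tol=cfg.pdr.accel_tol,
        gyro_tol=cfg.pdr.gyro_tol,
        smooth_window=cfg.pdr.smooth_window,
    )
    mask = pdr.smooth_zupt(raw, min_len=cfg.pdr.min_zupt_len)
    n_deleted = len(raw.runs()) - len(mask.runs())
    if n_deleted:
        logger.info("deleted %d short ZUPT runs (< %d samples)", n_deleted, cfg.pdr.min_zupt_len)
    seg = pdr.segment_strides(mask)
    pose = pdr.reconstruct_pose(rec, mask, tilt_gain=cfg.pdr.tilt_gain)

    r_s2i = fusion.fixture_rotation(cloud)
    r_star = fusion.compute_flat_correction(
        cloud,
        r_s2i,
        pose.rotation[mask.zupt1],
        contact_tol=cfg.fusion.contact_tol_mm * 1e-3,
        max_iter=cfg.fusion.max_iter,
    )
    calib = fusion.FrameCalibration(r_scan_to_imu=r_s2i, r_star=r_star, floor_offset=0.0)

    if not cloud.sole_dominates():
        logger.warning("sole does not dominate the underside; using all points for LP")
        lp_indices = np.arange(cloud.n_points)
    else:
        lp_indices = cloud.sole_indices

    world = fusion.transform_cloud_all(pose, calib, cloud)
    lp, lp_index = clr.lowest_point_trace(world, lp_indices)
    lp_by_zupt = [lp[s:e] for (s, e, _end) in seg]
    offset = fusion.compute_floor_offset(lp_by_zupt)
    calib.floor_offset = offset
    lp = lp - offset
    heel_z = world[:, cloud.heel_index, 2] - offset
    toe_z = world[:, cloud.toe_index, 2] - offset
    marker_z = (
        world[:, cloud.marker_index, 2] - offset if cloud.marker_index is not None else None
    )

    windows, strides, late_locs = [], [], []
    for sid, stride in enumerate(seg):
        win = clr.forward_swing_window(stride, heel_z, toe_z, mask)
        windows.append(win)
        sc = clr.stride_mfc(lp, lp_index, win, stride_id=sid, t_start=rec.time[stride[0]])
        strides.append(sc)
        if win.valid:
            late_locs.append(clr.late_swing_lowest_locations(win, lp_index, cloud))
    late = np.vstack(late_locs) if late_locs else np.empty((0, 2))
    n_invalid = sum(1 for s in strides if not s.valid)
    if n_invalid:
        logger.info("%d of %d strides invalid (irregular forward-swing window)", n_invalid, len(strides))
    return BoutResult(
        mask=mask,
        segmentation=seg,
        pose=pose,
        calibration=calib,
        lp=lp,
        lp_index=lp_index,
        heel_z=heel_z,
        toe_z=toe_z,
        marker_z=marker_z,
        strides=strides,
        windows=windows,
        late_swing_locations=late,
        n_deleted_runs=n_deleted,
    )


@dataclass
class ValidationReport:
    agreement: validation.AgreementResult
    pairs: list[dict] = field(default_factory=list)
    lag: int = 0
    peak_correlation: float = 0.0
    n_shape_mismatch: int = 0
    n_extraction_failures: int = 0


def validate_bout(
    bout: BoutResult,
    reference: MarkerTrajectory,
    imu_time: np.ndarray,
    participant_id: str = "P1",
    prominence_min: float = 5e-3,
) -> ValidationReport:
    """Compare the reconstructed marker height against a reference system.

    Resamples the reference onto the IMU timebase, aligns by global
    cross-correlation, extracts swing key points per matched stride from
    both sources, pairs them by matched rank (strides whose shape classes
    disagree are excluded and counted), and fits the mixed-effects limits
    of agreement to the differences (reconstruction minus reference, mm).
    """
    if bout.marker_z is None:
        raise validation.DataError("bout has no reconstructed marker trace")
    ref = validation.resample_trajectory(reference, imu_time)
    pairs, lag, peak = validation.match_strides(
        bout.marker_z, bout.segmentation, ref.position[:, 2], ref.gap_mask
    )
    diffs, pids, sids, table = [], [], [], []
    n_mismatch = 0
    n_fail = 0
    for sid, (a, b) in pairs:
        zupt_start, zupt_end, stride_end = bout.segmentation.strides[sid]
        swing = slice(zupt_end, stride_end)
        ref_swing = slice(a + (zupt_end - zupt_start), b)
        try:
            kp_rec = validation.extract_key_points(
                bout.marker_z[swing],
                prominence_min=prominence_min,
                participant_id=participant_id,
                stride_id=sid,
                source="reconstruction",
            )
            kp_ref = validation.extract_key_points(
                ref.position[ref_swing, 2],
                prominence_min=prominence_min,
                participant_id=participant_id,
                stride_id=sid,
                source="reference",
            )
        except validation.ExtractionError:
            n_fail += 1
            continue
        matched = validation.pair_key_points(kp_rec, kp_ref)
        if matched is None:
            n_mismatch += 1
            continue
        for name, hz_rec, hz_ref in matched:
            diffs.append((hz_rec - hz_ref) * 1e3)
            pids.append(participant_id)
            sids.append(sid)
            table.append(
                {
                    "participant_id": participant_id,
                    "stride_id": sid,
                    "keypoint": name,
                    "recon_mm": hz_rec * 1e3,
                    "ref_mm": hz_ref * 1e3,
                    "diff_mm": (hz_rec - hz_ref) * 1e3,
                }
            )
    if len(diffs) < 2:
        raise validation.InsufficientDataError("fewer than 2 key-point pairs matched")
    recon_mm = np.array([row["recon_mm"] for row in table])
    ref_mm = np.array([row["ref_mm"] for row in table])
    agreement = validation.limits_of_agreement(
        np.asarray(diffs), pids, sids, recon=recon_mm, ref=ref_mm
    )
    return ValidationReport(
        agreement=agreement,
        pairs=table,
        lag=lag,
        peak_correlation=peak,
        n_shape_mismatch=n_mismatch,
        n_extraction_failures=n_fail,
    )
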
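"""Validation against an optical reference: trajectory resampling, stride
matching, swing key-point extraction, and mixed-effects limits of agreement.

Toe-marker height trajectories from the reconstruction and from a reference
system (e.g. optical motion capture) are compared at key swing-phase
points: on an M-shaped swing path the two maxima (MaxP1, MaxP2) and the
minimum between them (MinP); on a single-peaked path only MaxP2.  Paired
differences (reconstruction minus reference) feed a random-intercept model
with stride nested in participant; the limits of agreement are
``bias +/- 1.96 * sqrt(var_participant + var_stride + var_residual)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal, stats

from .errors import AlignmentError, DataError, ExtractionError, InsufficientDataError
from .io import MarkerTrajectory
from .pdr import StrideSegmentation

logger = logging.getLogger(__name__)


@dataclass
class KeyPointSet:
    """Swing-phase toe-height key points for one stride and one source."""

    participant_id: str
    stride_id: int
    source: str  # "reconstruction" | "reference"
    max_p2: float
    max_p1: Optional[float] = None
    min_p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.max_p1 is not None:
            if self.min_p is None:
                raise DataError("max_p1 requires min_p")
            if self.min_p > min(self.max_p1, self.max_p2):
                raise DataError("min_p must not exceed the surrounding maxima")

    @property
    def shape_class(self) -> str:
        return "M" if self.max_p1 is not None else "single"


@dataclass
class AgreementResult:
    """Mixed-effects limits-of-agreement summary (millimeters)."""

    bias: float
    lower: float
    upper: float
    var_participant: float
    var_stride: float
    var_residual: float
    n: int
    r_squared: float

    @property
    def total_sd(self) -> float:
        return float(
            np.sqrt(self.var_participant + self.var_stride + self.var_residual)
        )


def resample_trajectory(
    traj: MarkerTrajectory, target_times: np.ndarray
) -> MarkerTrajectory:
    """Piecewise-linear resampling onto ``target_times``.

    A target sample is flagged as a gap when either source sample bracketing
    it is occluded.
    """
    target_times = np.asarray(target_times, dtype=float)
    if target_times.min() < traj.time[0] - 1e-12 or target_times.max() > traj.time[-1] + 1e-12:
        raise DataError("target times outside the reference time span")
    pos = np.column_stack(
        [np.interp(target_times, traj.time, traj.position[:, i]) for i in range(3)]
    )
    right = np.searchsorted(traj.time, target_times, side="left")
    right = np.clip(right, 0, len(traj) - 1)
    left = np.clip(right - 1, 0, len(traj) - 1)
    exact = np.isclose(traj.time[right], target_times)
    left = np.where(exact, right, left)
    gaps = traj.gap_mask[left] | traj.gap_mask[right]
    return MarkerTrajectory(time=target_times, position=pos, gap_mask=gaps)


def match_strides(
    recon_toe_z: np.ndarray,
    segmentation: StrideSegmentation,
    ref_toe_z: np.ndarray,
    ref_gap_mask: Optional[np.ndarray] = None,
    min_correlation: float = 0.5,
) -> tuple[list[tuple[int, tuple[int, int]]], int, float]:
    """Pair reconstruction strides with reference windows at a global lag.

    Both height signals must share the IMU timebase.  The lag maximizing
    the normalized cross-correlation aligns them; stride *n*'s window
    ``[start, end)`` maps to reference ``[start + lag, end + lag)``.  Pairs
    falling outside the reference or overlapping a reference gap are
    dropped.  Returns ``(pairs, lag, peak_correlation)``.
    """
    x = np.asarray(recon_toe_z, float) - np.mean(recon_toe_z)
    y = np.asarray(ref_toe_z, float) - np.mean(ref_toe_z)
    corr = signal.correlate(y, x, mode="full")
    lags = signal.correlation_lags(y.size, x.size, mode="full")
    denom = np.linalg.norm(x) * np.linalg.norm(y)
    if denom == 0:
        raise AlignmentError("flat signals cannot be aligned")
    best = int(np.argmax(corr))
    peak = float(corr[best] / denom)
    lag = int(lags[best])
    if peak < min_correlation:
        raise AlignmentError(
            f"cross-correlation peak {peak:.3f} below {min_correlation}"
        )
    pairs = []
    for sid, (start, _ze, end) in enumerate(segmentation):
        a, b = start + lag, end + lag
        if a < 0 or b > y.size:
            continue
        if ref_gap_mask is not None and np.any(ref_gap_mask[a:b]):
            continue
        pairs.append((sid, (a, b)))
    return pairs, lag, peak


def extract_key_points(
    toe_z: np.ndarray,
    prominence_min: float = 5e-3,
    participant_id: str = "",
    stride_id: int = 0,
    source: str = "reconstruction",
) -> KeyPointSet:
    """Key maxima/minimum of one stride's swing-phase toe-height trace.

    Local maxima with topographic prominence >= ``prominence_min`` define
    the shape class: two or more give MaxP1 (first), MaxP2 (last) and MinP
    (minimum strictly between them); exactly one gives MaxP2 only.
    """
    toe_z = np.asarray(toe_z, dtype=float)
    if toe_z.size < 5:
        raise ExtractionError("need at least 5 swing samples")
    peaks, _props = signal.find_peaks(toe_z, prominence=prominence_min)
    if peaks.size == 0:
        raise ExtractionError("no maximum with sufficient prominence")
    if peaks.size == 1:
        return KeyPointSet(
            participant_id=participant_id,
            stride_id=stride_id,
            source=source,
            max_p2=float(toe_z[peaks[0]]),
        )
    k1, k2 = int(peaks[0]), int(peaks[-1])
    min_p = float(np.min(toe_z[k1 + 1 : k2]))
    return KeyPointSet(
        participant_id=participant_id,
        stride_id=stride_id,
        source=source,
        max_p1=float(toe_z[k1]),
        min_p=min_p,
        max_p2=float(toe_z[k2]),
    )


def pair_key_points(
    recon: KeyPointSet, ref: KeyPointSet
) -> Optional[list[tuple[str, float, float]]]:
    """Matched-rank height pairs, or None when the shape classes disagree."""
    if recon.shape_class != ref.shape_class:
        return None
    pairs = [("max_p2", recon.max_p2, ref.max_p2)]
    if recon.shape_class == "M":
        pairs = [
            ("max_p1", recon.max_p1, ref.max_p1),
            ("min_p", recon.min_p, ref.min_p),
            ("max_p2", recon.max_p2, ref.max_p2),
        ]
    return pairs


def _nested_anova_components(
    d: np.ndarray, pid: np.ndarray, sid: np.ndarray
) -> tuple[float, float, float]:
    """Method-of-moments nested variance components (clipped at zero).

    Handles unbalanced and degenerate layouts: levels with a single group
    contribute zero variance, and with one observation per stride the
    stride and residual components are not separable — the remaining
    variance is assigned to the residual.
    """
    participants = np.unique(pid)
    cells = np.unique(np.char.add(np.char.add(pid.astype(str), "|"), sid.astype(str)))
    n = d.size
    grand = d.mean()
    # residual: within-cell
    ss_e = 0.0
    df_e = 0
    cell_key = np.char.add(np.char.add(pid.astype(str), "|"), sid.astype(str))
    cell_means = {}
    cell_sizes = {}
    for c in cells:
        m = cell_key == c
        cell_means[c] = d[m].mean()
        cell_sizes[c] = int(m.sum())
        ss_e += float(np.sum((d[m] - cell_means[c]) ** 2))
        df_e += cell_sizes[c] - 1
    var_e = ss_e / df_e if df_e > 0 else 0.0
    # stride within participant
    ss_s = 0.0
    df_s = 0
    n0_list = []
    for p in participants:
        m = pid == p
        keys = np.unique(cell_key[m])
        if keys.size < 2:
            continue
        pm = d[m].mean()
        sizes = np.array([cell_sizes[c] for c in keys], float)
        means = np.array([cell_means[c] for c in keys])
        ss_s += float(np.sum(sizes * (means - pm) ** 2))
        df_s += keys.size - 1
        n0_list.append((sizes.sum() - np.sum(sizes**2) / sizes.sum()) / (keys.size - 1))
    if df_s > 0 and df_e > 0:
        n0 = float(np.mean(n0_list))
        var_s = max(0.0, (ss_s / df_s - var_e) / n0)
    elif df_s > 0:
        # one observation per stride: stride and residual are confounded
        var_s = 0.0
        var_e = ss_s / df_s
    else:
        var_s = 0.0
    # participant
    if participants.size >= 2:
        sizes_p = np.array([(pid == p).sum() for p in participants], float)
        means_p = np.array([d[pid == p].mean() for p in participants])
        ss_p = float(np.sum(sizes_p * (means_p - grand) ** 2))
        df_p = participants.size - 1
        ms_p = ss_p / df_p
        # expected MS coefficients for the nested layout
        c_s = 0.0
        for p in participants:
            m = pid == p
            keys = np.unique(cell_key[m])
            sizes = np.array([cell_sizes[c] for c in keys], float)
            c_s += np.sum(sizes**2) / sizes.sum()
        c_s = (d.size - c_s) / df_p if participants.size > 1 else 0.0
        c_p = (n - np.sum(sizes_p**2) / n) / df_p
        # E[MS_p] ~= var_e + k_s var_s + c_p var_p with k_s between cell sizes;
        # use the balanced-form coefficient (mean cell size within participant)
        k_s = float(np.mean([cell_sizes[c] for c in cells]))
        var_p = max(0.0, (ms_p - var_e - k_s * var_s) / c_p)
    else:
        var_p = 0.0
    return var_p, var_s, var_e


def _balanced_layout(pid: np.ndarray, sid: np.ndarray) -> Optional[tuple[int, int, int]]:
    """(a, b, r) for a balanced nested layout, else None."""
    participants = np.unique(pid)
    a = participants.size
    b = None
    r = None
    for p in participants:
        strides = sid[pid == p]
        u, counts = np.unique(strides, return_counts=True)
        if b is None:
            b, r = u.size, counts[0]
        if u.size != b or np.any(counts != r):
            return None
    if a < 2 or b < 2 or r < 2:
        return None
    return a, int(b), int(r)


def _balanced_reml(
    d: np.ndarray, pid: np.ndarray, sid: np.ndarray, a: int, b: int, r: int
) -> tuple[float, float, float]:
    """Closed-form variance components for a balanced nested design.

    These are the classical nested-ANOVA estimators, which coincide with
    the REML solution whenever all components are interior (non-negative);
    negative estimates are clipped at zero.
    """
    key = np.char.add(np.char.add(pid.astype(str), "|"), sid.astype(str))
    cells, inv = np.unique(key, return_inverse=True)
    cell_mean = np.bincount(inv, weights=d) / np.bincount(inv)
    cell_pid = []
    for c in cells:
        cell_pid.append(c.split("|")[0])
    cell_pid = np.asarray(cell_pid)
    participants, pinv = np.unique(cell_pid, return_inverse=True)
    p_mean = np.bincount(pinv, weights=cell_mean) / np.bincount(pinv)
    grand = d.mean()
    ms_e = float(np.sum((d - cell_mean[inv]) ** 2)) / (a * b * (r - 1))
    ms_s = r * float(np.sum((cell_mean - p_mean[pinv]) ** 2)) / (a * (b - 1))
    ms_p = b * r * float(np.sum((p_mean - grand) ** 2)) / (a - 1)
    var_e = ms_e
    var_s = max(0.0, (ms_s - ms_e) / r)
    var_p = max(0.0, (ms_p - ms_s) / (b * r))
    return var_p, var_s, var_e


def limits_of_agreement(
    differences: np.ndarray,
    participant_ids: Sequence,
    stride_ids: Sequence,
    recon: Optional[np.ndarray] = None,
    ref: Optional[np.ndarray] = None,
) -> AgreementResult:
    """Mixed-effects limits of agreement for method differences (mm).

    Fits ``difference ~ 1`` with random intercepts for participant and for
    stride nested within participant (REML), and returns the bias with
    limits ``bias +/- 1.96 * total SD``.  Balanced designs use the exact
    closed-form components; unbalanced designs use statsmodels MixedLM,
    falling back to method-of-moments components if the fit is singular.
    ``recon``/``ref`` optionally supply the paired heights whose squared
    Pearson correlation is reported as R^2.
    """
    d = np.asarray(differences, dtype=float)
    pid = np.asarray(participant_ids).astype(str)
    sid = np.asarray(stride_ids).astype(str)
    if d.size < 2:
        raise InsufficientDataError("need at least 2 differences")
    if not (d.size == pid.size == sid.size):
        raise DataError("differences and id vectors must have equal length")
    # nesting contract: each stride id belongs to exactly one participant
    for s in np.unique(sid):
        if np.unique(pid[sid == s]).size > 1:
            raise DataError(f"stride id {s!r} appears under multiple participants")

    r_squared = float("nan")
    if recon is not None and ref is not None:
        rr = stats.pearsonr(np.asarray(recon, float), np.asarray(ref, float))
        r_squared = float(rr.statistic**2)

    if np.ptp(d) == 0.0:
        c = float(d[0])
        return AgreementResult(
            bias=c, lower=c, upper=c,
            var_participant=0.0, var_stride=0.0, var_residual=0.0,
            n=d.size, r_squared=r_squared,
        )

    bias = float(d.mean())
    layout = _balanced_layout(pid, sid)
    if layout is not None:
        var_p, var_s, var_e = _balanced_reml(d, pid, sid, *layout)
        # GLS/REML intercept for a balanced design is the grand mean
    elif np.unique(pid).size >= 2:
        try:
            import pandas as pd
            from statsmodels.regression.mixed_linear_model import MixedLM

            df = pd.DataFrame({"d": d, "participant": pid, "stride": sid})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = MixedLM.from_formula(
                    "d ~ 1",
                    groups="participant",
                    re_formula="1",
                    vc_formula={"stride": "0 + C(stride)"},
                    data=df,
                )
                fit = model.fit(reml=True)
            var_p = float(fit.cov_re.iloc[0, 0])
            var_s = float(fit.vcomp[0]) if fit.vcomp.size else 0.0
            var_e = float(fit.scale)
            bias = float(fit.params.iloc[0])
            if not all(map(np.isfinite, (var_p, var_s, var_e, bias))):
                raise ValueError("non-finite mixed-model estimates")
        except Exception as exc:
            logger.warning(
                "mixed-model fit failed (%s); falling back to method-of-moments",
                exc,
            )
            var_p, var_s, var_e = _nested_anova_components(d, pid, sid)
            bias = float(d.mean())
    else:
        # single participant (or otherwise degenerate): method of moments
        var_p, var_s, var_e = _nested_anova_components(d, pid, sid)

    total_sd = float(np.sqrt(var_p + var_s + var_e))
    return AgreementResult(
        bias=bias,
        lower=bias - 1.96 * total_sd,
        upper=bias + 1.96 * total_sd,
        var_participant=var_p,
        var_stride=var_s,
        var_residual=var_e,
        n=d.size,
        r_squared=r_squared,
    )
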
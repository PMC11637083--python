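"""Instantaneous lowest point, forward-swing windows, per-stride minimum
foot clearance (mFC), and the late-swing lowest-point density map.

The instantaneous clearance LP(k) is the height of the lowest cloud point at
sample k.  Forward swing runs from the stride's maximum heel height to its
maximum toe height; mFC is the minimum of LP over that window.  Negative
mFC is reported as-is — it marks floor contact (scuffing) rather than an
error.  The late-swing analysis maps where on the sole the lowest point
fell during the final third of forward swing, smoothed with a Gaussian
kernel over a grid covering the sole and normalized by the grid maximum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError
from .io import ScanPointCloud
from .pdr import ZuptMask


@dataclass
class ForwardSwingWindow:
    k_max_heel: int
    k_max_toe: int
    valid: bool


@dataclass
class StrideClearance:
    """Per-stride clearance summary (heights in meters internally)."""

    stride_id: int
    t_start: float
    valid: bool
    mfc: Optional[float] = None
    k_mfc: Optional[int] = None
    i_mfc: Optional[int] = None
    k_max_heel: Optional[int] = None
    k_max_toe: Optional[int] = None

    @property
    def mfc_mm(self) -> Optional[float]:
        return None if self.mfc is None else self.mfc * 1e3


@dataclass
class SoleHeatmap:
    """Normalized lowest-point density over a sole grid (scan frame)."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    density: np.ndarray  # shape (len(grid_y), len(grid_x)), in [0, 1]
    bandwidth: float
    marginal_x: np.ndarray  # counts per grid_x-spaced bin
    marginal_y: np.ndarray
    n_locations: int


def lowest_point_trace(
    world_clouds: np.ndarray, sole_indices: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample lowest-point height and its cloud index.

    ``world_clouds`` is (n_samples, N, 3).  The minimum is taken over the
    sole subset (equivalent to all points whenever the sole dominates the
    underside); ties resolve to the smallest point index.
    """
    sole_indices = np.asarray(sole_indices, dtype=int)
    if sole_indices.size == 0:
        raise InsufficientDataError("sole_indices is empty")
    z = world_clouds[:, sole_indices, 2]
    j = np.argmin(z, axis=1)  # first minimum on ties
    lp = z[np.arange(z.shape[0]), j]
    return lp, sole_indices[j]


def forward_swing_window(
    stride: tuple[int, int, int],
    heel_z: np.ndarray,
    toe_z: np.ndarray,
    zupt: ZuptMask,
) -> ForwardSwingWindow:
    """Window from maximum heel height to maximum toe height in a stride.

    Invalid (never an exception) when the toe peak does not follow the heel
    peak or either falls inside a stance run — the definition of forward
    swing assumes heel-first lift-off and may not hold for all gaits.
    """
    zupt_start, _zupt_end, stride_end = stride
    seg = slice(zupt_start, stride_end)
    k_heel = zupt_start + int(np.argmax(heel_z[seg]))
    k_toe = zupt_start + int(np.argmax(toe_z[seg]))
    valid = bool(
        k_heel < k_toe and not zupt.flags[k_heel] and not zupt.flags[k_toe]
    )
    return ForwardSwingWindow(k_max_heel=k_heel, k_max_toe=k_toe, valid=valid)


def stride_mfc(
    lp: np.ndarray,
    lp_index: np.ndarray,
    window: ForwardSwingWindow,
    stride_id: int = 0,
    t_start: float = 0.0,
) -> StrideClearance:
    """Minimum foot clearance over the (inclusive) forward-swing window."""
    if not window.valid:
        return StrideClearance(stride_id=stride_id, t_start=t_start, valid=False)
    sl = slice(window.k_max_heel, window.k_max_toe + 1)
    k_rel = int(np.argmin(lp[sl]))
    k_mfc = window.k_max_heel + k_rel
    return StrideClearance(
        stride_id=stride_id,
        t_start=t_start,
        valid=True,
        mfc=float(lp[k_mfc]),
        k_mfc=k_mfc,
        i_mfc=int(lp_index[k_mfc]),
        k_max_heel=window.k_max_heel,
        k_max_toe=window.k_max_toe,
    )


def late_swing_lowest_locations(
    window: ForwardSwingWindow, lp_index: np.ndarray, cloud: ScanPointCloud
) -> np.ndarray:
    """Scan-frame (x, y) of the lowest point over the final third of
    forward swing, one row per sample.

    The late-swing window is ``[k_heel + ceil(2 (k_toe - k_heel) / 3),
    k_toe]`` — the ceiling keeps it from reaching into the middle third.
    """
    if not window.valid:
        return np.empty((0, 2))
    width = window.k_max_toe - window.k_max_heel
    if width < 2:
        warnings.warn("forward-swing window shorter than 3 samples; no late swing")
        return np.empty((0, 2))
    start = window.k_max_heel + math.ceil(2 * width / 3)
    ks = np.arange(start, window.k_max_toe + 1)
    return cloud.points[lp_index[ks], :2].copy()


def sole_density_heatmap(
    locations: np.ndarray,
    cloud: ScanPointCloud,
    spacing: float = 2e-3,
    sigma: float = 10e-3,
) -> SoleHeatmap:
    """Gaussian-kernel density of lowest-point locations over the sole.

    A uniform grid covers the sole's bounding box padded by 3 sigma;
    ``density(node) = sum_loc exp(-|node - loc|^2 / (2 sigma^2))``, divided
    by its maximum (all zero when no location contributed).  Marginal
    histograms count raw locations in grid-spaced bins.
    """
    if spacing <= 0 or sigma <= 0:
        raise ValueError("spacing and sigma must be positive")
    locations = np.asarray(locations, dtype=float).reshape(-1, 2)
    sole = cloud.points[cloud.sole_indices]
    pad = 3 * sigma
    x0, x1 = sole[:, 0].min() - pad, sole[:, 0].max() + pad
    y0, y1 = sole[:, 1].min() - pad, sole[:, 1].max() + pad
    grid_x = x0 + spacing * np.arange(int(np.floor((x1 - x0) / spacing)) + 1)
    grid_y = y0 + spacing * np.arange(int(np.floor((y1 - y0) / spacing)) + 1)
    density = np.zeros((grid_y.size, grid_x.size))
    if locations.shape[0] > 0:
        dx2 = (grid_x[None, :] - locations[:, 0][:, None]) ** 2  # (m, nx)
        dy2 = (grid_y[None, :] - locations[:, 1][:, None]) ** 2  # (m, ny)
        gx = np.exp(-dx2 / (2 * sigma**2))
        gy = np.exp(-dy2 / (2 * sigma**2))
        density = np.einsum("my,mx->yx", gy, gx)
        density /= density.max()
    edges_x = np.concatenate([grid_x - spacing / 2, [grid_x[-1] + spacing / 2]])
    edges_y = np.concatenate([grid_y - spacing / 2, [grid_y[-1] + spacing / 2]])
    marginal_x, _ = np.histogram(locations[:, 0], bins=edges_x)
    marginal_y, _ = np.histogram(locations[:, 1], bins=edges_y)
    return SoleHeatmap(
        grid_x=grid_x,
        grid_y=grid_y,
        density=density,
        bandwidth=sigma,
        marginal_x=marginal_x,
        marginal_y=marginal_y,
        n_locations=int(locations.shape[0]),
    )


def clearance_trend(
    strides: Sequence[StrideClearance],
) -> tuple[float, float, float]:
    """Ordinary least-squares trend of mFC against stride start time.

    Returns ``(slope_mm_per_min, intercept_mm, p_value)`` with the exact
    two-sided t-test p-value for zero slope.  Supports fatigue analyses of
    the six-minute-walk-test kind, where clearance is expected to drift
    over the bout.
    """
    valid = [s for s in strides if s.valid and s.mfc is not None]
    if len(valid) < 3:
        raise InsufficientDataError(
            f"need >= 3 valid strides for a trend, got {len(valid)}"
        )
    t_min = np.array([s.t_start for s in valid]) / 60.0
    y_mm = np.array([s.mfc for s in valid]) * 1e3
    if np.ptp(y_mm) == 0.0:
        return 0.0, float(y_mm[0]), 1.0
    res = stats.linregress(t_min, y_mm)
    p = float(res.pvalue)
    if not np.isfinite(p):  # zero residual variance, nonzero slope
        p = 0.0
    return float(res.slope), float(res.intercept), p
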
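"""Run configuration: per-module parameter sections, loadable from YAML."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .errors import DataError, FormatError


@dataclass
class PdrConfig:
    accel_tol: float = 0.8  # m/s^2, |accel norm - g| stance threshold
    gyro_tol: float = 0.3  # rad/s stance threshold
    smooth_window: int = 5  # samples, centered moving average of the norms
    min_zupt_len: int = 15  # samples, shorter stance runs are deleted
    tilt_gain: float = 0.02  # per-sample complementary tilt gain in stance


@dataclass
class FusionConfig:
    contact_tol_mm: float = 3.0
    max_iter: int = 20
    max_rstar_deg: float = 15.0


@dataclass
class ClearanceConfig:
    heatmap_spacing_mm: float = 2.0
    heatmap_sigma_mm: float = 10.0


@dataclass
class ValidationConfig:
    prominence_min_mm: float = 5.0
    min_correlation: float = 0.5


@dataclass
class RunConfig:
    imu_path: Optional[str] = None
    scan_path: Optional[str] = None
    marker_path: Optional[str] = None
    output_dir: str = "out"
    log_level: str = "INFO"
    imu_dialect: dict = field(default_factory=dict)
    pdr: PdrConfig = field(default_factory=PdrConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    clearance: ClearanceConfig = field(default_factory=ClearanceConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)

    def __post_init__(self) -> None:
        checks = [
            (self.pdr.accel_tol > 0, "pdr.accel_tol must be > 0"),
            (self.pdr.gyro_tol > 0, "pdr.gyro_tol must be > 0"),
            (self.pdr.smooth_window >= 1, "pdr.smooth_window must be >= 1"),
            (self.pdr.min_zupt_len >= 1, "pdr.min_zupt_len must be >= 1"),
            (0 < self.pdr.tilt_gain < 1, "pdr.tilt_gain must lie in (0, 1)"),
            (self.fusion.contact_tol_mm > 0, "fusion.contact_tol_mm must be > 0"),
            (self.fusion.max_iter >= 1, "fusion.max_iter must be >= 1"),
            (self.clearance.heatmap_spacing_mm > 0, "heatmap spacing must be > 0"),
            (self.clearance.heatmap_sigma_mm > 0, "heatmap sigma must be > 0"),
            (self.validation.prominence_min_mm > 0, "prominence must be > 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise DataError(msg)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such config file: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError("config must be a YAML mapping")
    sections = {
        "pdr": PdrConfig,
        "fusion": FusionConfig,
        "clearance": ClearanceConfig,
        "validation": ValidationConfig,
    }
    kwargs = {}
    for key, value in raw.items():
        if key in sections:
            if not isinstance(value, dict):
                raise FormatError(f"config section {key!r} must be a mapping")
            try:
                kwargs[key] = sections[key](**value)
            except TypeError as exc:
                raise FormatError(f"bad key in config section {key!r}: {exc}") from exc
        elif key in (
            "imu_path",
            "scan_path",
            "marker_path",
            "output_dir",
            "log_level",
            "imu_dialect",
        ):
            kwargs[key] = value
        else:
            raise FormatError(f"unknown config key {key!r}")
    return RunConfig(**kwargs)
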
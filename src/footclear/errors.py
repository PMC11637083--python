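"""Exception hierarchy shared by all footclear modules.

Each error class carries the process exit code used by the command-line
interface (0 = success, 2 = format/data error, 3 = calibration error,
4 = alignment or insufficient data).
"""


class FootclearError(Exception):
    """Base class for all footclear errors."""

    exit_code = 1


class FormatError(FootclearError):
    """A file does not follow the documented CSV dialect."""

    exit_code = 2


class DataError(FootclearError):
    """A file parses but its contents violate a contract (e.g. time order)."""

    exit_code = 2


class CalibrationError(FootclearError):
    """Scan fixture axes or the flat-foot correction are unusable."""

    exit_code = 3


class PlaneFitError(CalibrationError):
    """The support-plane fit degenerated (collinear contact set)."""


class SegmentationError(FootclearError):
    """Too few zero-velocity runs to segment strides."""

    exit_code = 4


class ReconstructionError(FootclearError):
    """Dead-reckoning reconstruction cannot proceed (e.g. empty ZUPT mask)."""

    exit_code = 4


class AlignmentError(FootclearError):
    """Reconstruction and reference trajectories could not be aligned."""

    exit_code = 4


class InsufficientDataError(FootclearError):
    """Not enough valid observations for the requested statistic."""

    exit_code = 4


class ExtractionError(FootclearError):
    """No qualifying key point could be extracted from a swing trace."""

    exit_code = 4
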
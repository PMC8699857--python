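"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`ThermasymError` so callers (and the
CLI) can map failures onto distinct exit codes without string matching.
"""


class ThermasymError(Exception):
    """Base class for all package errors."""


class InputError(ThermasymError):
    """Invalid file, format, or parameter supplied by the caller."""


class FormatError(InputError):
    """Malformed on-disk data (ragged CSV, wrong PNG mode, missing sidecar)."""


class ValidationError(InputError):
    """Data violates a domain invariant (e.g. implausible temperatures)."""


class ParameterError(InputError):
    """A parameter outside its allowed set."""


class DegenerateRangeError(ThermasymError):
    """A value range collapsed to a point (constant image, hi <= lo)."""


class SizeError(ThermasymError):
    """Input too small for the requested operation."""


class SegmentationError(ThermasymError):
    """Failure inside the ROI segmentation chain; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class DegenerateHistogramError(SegmentationError):
    def __init__(self, message: str = "image has fewer than 2 distinct levels"):
        super().__init__("otsu", message)


class LandmarkError(SegmentationError):
    """A key-point search window contained no candidate; names the landmark."""

    def __init__(self, landmark: str, message: str = ""):
        self.landmark = landmark
        super().__init__("keypoints", f"landmark '{landmark}' not found. {message}".strip())


class LayoutError(SegmentationError):
    def __init__(self, message: str):
        super().__init__("layout", message)


class ModelingError(ThermasymError):
    """Failure in statistics, classification, or cross-validation."""


class GroupingError(ModelingError):
    """Cohort does not contain the two groups an operation requires."""


class ConstraintError(ModelingError):
    """A cross-validation split constraint cannot be satisfied."""


class ConfigError(ThermasymError):
    """Inconsistent generator or pipeline configuration."""
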
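"""Exception hierarchy shared by all pipeline stages."""


class SpheroquantError(Exception):
    """Base class for all package errors."""


class ValidationError(SpheroquantError, ValueError):
    """Invalid argument values (non-finite, non-positive, wrong shape ...)."""


class GeometryError(ValidationError):
    """Geometrically impossible configuration (e.g. spheroid wider than channel)."""


class TrackingError(SpheroquantError):
    """Too few detections to follow a spheroid through a frame sequence."""


class FitError(SpheroquantError):
    """Velocity fit failed, e.g. no terminal plateau in the track."""


class PipelineError(SpheroquantError):
    """Statistical cleaning pipeline cannot proceed (too few values left)."""


class DegenerateVarianceError(SpheroquantError):
    """Zero pooled variance with unequal means: the t statistic is undefined."""


class CalibrationError(SpheroquantError):
    """Standard curve cannot be inverted (zero slope or degenerate standards)."""


class NoSpheroidError(SpheroquantError):
    """No spheroid component detected in a bright-field image."""


class GeneratorError(SpheroquantError):
    """Synthetic scenario is unrealizable (frame too short, density too high)."""


class SchemaError(SpheroquantError, ValueError):
    """Tabular/config input violates the declared schema."""


class IOFormatError(SpheroquantError, IOError):
    """Unreadable or inconsistent image/table file."""
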
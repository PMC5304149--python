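"""Exception hierarchy.

Every error raised by this package derives from :class:`FlimError`, so callers
can catch one type at pipeline boundaries while tests can assert on the
specific condition.
"""


class FlimError(Exception):
    """Base class for all errors raised by flimphasor."""


class InvalidInputError(FlimError, ValueError):
    """Input data violates a structural precondition (shape, sign, dtype)."""


class InvalidSpecError(FlimError, ValueError):
    """A synthetic-data or acquisition specification is inconsistent."""


class EmptyPixelError(FlimError):
    """A pixel has zero total intensity inside the summation window."""


class EmptyCloudError(FlimError):
    """No pixel survived the intensity threshold."""


class CalibrationError(FlimError):
    """Reference phasor is degenerate (mean at the origin)."""


class DegenerateCloudError(FlimError):
    """All points coincide; no line can be fitted."""


class AmbiguousDirectionError(FlimError):
    """Cloud is isotropic; the principal direction is not identifiable."""


class NoIntersectionError(FlimError):
    """Fitted line misses the universal circle."""


class TangentLineError(FlimError):
    """Fitted line is tangent to (or only grazes) the universal semicircle."""


class DegenerateEllipseError(FlimError):
    """Covariance of the cloud is singular; the confidence ellipse collapses."""

    def __init__(self, message: str, eigenvalue: float | None = None):
        super().__init__(message)
        self.eigenvalue = eigenvalue


class ConvergenceError(FlimError):
    """Decay fit did not converge and no usable iterate exists."""


class AnalysisStageError(FlimError):
    """Wraps an error raised inside a pipeline stage, naming the stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


class UnknownFormatError(FlimError):
    """File format could not be determined or is unsupported."""


class AxisOrderError(FlimError):
    """Array axes of an input stack cannot be matched to (row, col, channel)."""


class MissingMetadataError(FlimError):
    """A reader is missing acquisition metadata it cannot invent."""


class CapabilityError(FlimError):
    """An optional dependency required for this format is not installed."""
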
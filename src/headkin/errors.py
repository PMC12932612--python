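"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`HeadkinError` so callers (and the
CLI) can map failure families to distinct exit codes.
"""


class HeadkinError(Exception):
    """Base class for all errors raised by headkin."""


class FormatError(HeadkinError):
    """A file or token does not conform to the expected on-disk format."""


class IntegrityError(HeadkinError):
    """Data violates a structural invariant (duplicates, non-monotonic time)."""


class ParameterError(HeadkinError):
    """A parameter is outside its valid domain."""


class DegenerateInputError(HeadkinError):
    """Input is too small or too uniform for the operation to be defined."""


class ShapeError(HeadkinError):
    """An array does not have the required shape."""


class RankError(HeadkinError):
    """A design matrix is rank deficient."""


class ConvergenceError(HeadkinError):
    """Iterative estimation failed to converge."""


class InferenceError(HeadkinError):
    """A variance or degrees-of-freedom computation is ill-defined."""


class UndefinedCorrelationError(DegenerateInputError):
    """A correlation is undefined because one variable has zero variance."""


class SensorRangeWarning(UserWarning):
    """A gyroscope sample exceeds the sensor's nominal range (non-fatal)."""
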
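"""Exception hierarchy for the tapkin pipeline.

Every failure mode that a caller may want to catch programmatically has its
own class; all inherit from :class:`TapkinError`.
"""


class TapkinError(Exception):
    """Base class for all tapkin errors."""


class InvalidParameterError(TapkinError, ValueError):
    """A generator or filter parameter violates its invariants."""


class SchemaError(TapkinError, ValueError):
    """An input file or table does not match the expected schema."""


class OrderingError(TapkinError, ValueError):
    """Frame indices or timestamps are not strictly increasing."""


class EmptySignalError(TapkinError, ValueError):
    """A sequence or signal contains no usable frames."""


class AngleRangeError(TapkinError, ValueError):
    """An angle lies outside the representable [0, 180) degree range."""


class DegenerateGeometryError(TapkinError, ValueError):
    """A fingertip coincides with the hand base; the angle is undefined."""


class ConfigurationError(TapkinError, ValueError):
    """A configuration value is inconsistent (e.g. cutoff above Nyquist)."""


class InsufficientMovementError(TapkinError, ValueError):
    """Fewer than two complete tapping cycles were found in a trial."""


class InsufficientTapsError(TapkinError, ValueError):
    """Too few taps to compute the feature set (need >= 4)."""


class SegmentationIntegrityError(TapkinError, ValueError):
    """A segmentation produced a non-positive tap amplitude."""


class CannotSynthesizeError(TapkinError, ValueError):
    """A class has too few rows for synthetic oversampling."""


class StratificationError(TapkinError, ValueError):
    """A cross-validation fold degenerated to a single class."""


class TierDegeneracyError(TapkinError, ValueError):
    """A tier's training subset contains only one class."""


class UndefinedMetricError(TapkinError, ValueError):
    """A metric is undefined for the given evaluation set."""


class UsageError(TapkinError, ValueError):
    """The operation was invoked with unusable inputs."""
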
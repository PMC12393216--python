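"""Exception hierarchy shared across the package."""


class RheoError(Exception):
    """Base class for all package errors."""


class InvalidSpecificationError(RheoError, ValueError):
    """A chamber/cohort/simulation specification violates its invariants."""


class InvalidArgumentError(RheoError, ValueError):
    """An operation received an argument outside its domain."""


class InsufficientDataError(RheoError, ValueError):
    """Not enough samples/tracks/pairs to perform the estimate."""


class InsufficientDurationError(InsufficientDataError):
    """A track or trace is shorter than the analysis window requires."""


class DegenerateFitError(RheoError, ValueError):
    """A regression problem has no usable solution (e.g. all-zero regressor)."""


class ZeroVarianceError(RheoError, ValueError):
    """Equipartition estimate undefined: the trace has zero variance."""


class UndefinedAngleError(RheoError, ValueError):
    """Trajectory angle undefined because net displacement is zero."""


class UndefinedRatioError(RheoError, ZeroDivisionError):
    """Orientation ratio undefined: no filaments in the denominator range."""


class InvalidBinningError(RheoError, ValueError):
    """Angular bin width does not divide the full circle."""


class NoEventsError(RheoError, ValueError):
    """Event frequency undefined: no directional movements detected."""


class NonUniformSamplingError(RheoError, ValueError):
    """A trace is not uniformly sampled and resampling is disabled."""
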
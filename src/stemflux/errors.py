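"""Exception hierarchy for the stemflux pipeline.

Every stage raises a subclass of :class:`StemfluxError` so callers can
distinguish pipeline failures from programming errors.
"""


class StemfluxError(Exception):
    """Base class for all stemflux errors."""


class ConfigurationError(StemfluxError):
    """A configuration value is missing, non-finite or out of range."""


class ValidationError(StemfluxError):
    """Input data violate a documented precondition (range, emptiness)."""


class AlignmentError(StemfluxError):
    """Two series that must share a timestamp grid do not."""


class StateError(StemfluxError):
    """An operation was applied in the wrong order (e.g. double correction)."""


class IdentityError(StemfluxError):
    """Traces that must belong to the same tree do not."""


class ParameterError(StemfluxError):
    """An analysis parameter (e.g. filter cutoff) is out of its valid range."""


class DataQualityError(StemfluxError):
    """Too many gaps or otherwise unusable data for the requested analysis."""


class DataQuantityError(StemfluxError):
    """Not enough valid observations for the requested fit."""


class NumericalError(StemfluxError):
    """The numerical scheme left its stability region."""


class EstimationError(StemfluxError):
    """An estimator could not produce a defined answer (flat or short input)."""


class CollinearityError(StemfluxError):
    """Perfectly collinear predictors were passed to a regression."""
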
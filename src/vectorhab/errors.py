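"""Exception hierarchy shared across the pipeline stages."""


class VectorhabError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VectorhabError):
    """A config value or requested layer/stage is invalid or missing."""


class InvalidInputError(VectorhabError, ValueError):
    """A scalar or array input violates an operation's precondition."""


class DataIntegrityError(VectorhabError):
    """Input data contradicts a physical invariant (e.g. t_max < t_min)."""


class OutOfDomainError(VectorhabError):
    """A query point falls outside the grid's bounding box."""


class IncompleteSequenceError(VectorhabError):
    """A feature sequence cannot be filled from the available days."""


class EmptyInputError(VectorhabError):
    """No usable records/values remain after filtering."""


class SamplingError(VectorhabError):
    """Pseudo-absence or split sampling cannot be completed."""


class InsufficientDataError(VectorhabError):
    """Too few observations for the requested statistic or fit."""


class UndefinedSeasonError(VectorhabError):
    """A daily risk series has no mass, so no season window exists."""


class AlignmentError(VectorhabError):
    """Two rasters do not share a common grid."""


class DependencyError(VectorhabError):
    """A pipeline stage's upstream artifact is missing."""
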
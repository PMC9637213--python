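"""Exception hierarchy shared by all eegcsp modules."""


class EegError(Exception):
    """Base class for all eegcsp errors."""


class ConfigurationError(EegError):
    """Invalid configuration (duplicate montage entries, bad fractions, ...)."""


class FormatError(EegError):
    """On-disk record or sidecar is malformed or inconsistent."""


class SchemaError(EegError):
    """In-memory objects disagree on channel sets, label order or shapes."""


class UnknownChannelError(EegError):
    """A channel label does not resolve on the montage or record."""


class FilterError(EegError):
    """Band-pass filtering cannot be applied (bad band, record too short)."""


class BoundsError(EegError):
    """An interval specification does not fit inside its epoch."""


class SchedulingError(EegError):
    """Synthetic event onsets cannot be scheduled inside the record."""


class EmptyAverageError(EegError):
    """An average was requested over zero intervals."""


class DegenerateInputError(EegError):
    """Numerically degenerate input (zero trace, zero power, empty series)."""


class FeatureError(EegError):
    """A feature value is undefined (e.g. log-variance of a constant signal)."""


class MaskInfeasibleError(EegError):
    """A Laplacian mask cannot be computed because neighbors are missing."""
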
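"""Exception hierarchy for the swimsyn pipeline.

Stage-level errors map onto CLI exit codes: ConfigError -> 2,
DependencyError -> 3, any DataError subclass -> 4.
"""


class SwimsynError(Exception):
    """Base class for all package errors."""


class ConfigError(SwimsynError):
    """Invalid or unreadable pipeline configuration."""


class DependencyError(SwimsynError):
    """A required upstream artifact is missing."""


class DataError(SwimsynError):
    """Invalid data reaching an operation."""


class InvalidDesignError(DataError):
    """Impossible simulation/study design (e.g. more synergies than muscles)."""


class InvalidParameterError(DataError):
    """Out-of-domain numeric parameter."""


class InvalidBandError(InvalidParameterError):
    """Filter band incompatible with the sampling rate."""


class InvalidMvcError(DataError):
    """MVC trials missing or degenerate (would divide by zero)."""


class EventStreamError(DataError):
    """Cycle/phase event timestamps missing, unordered, or out of range."""


class DegenerateSegmentError(DataError):
    """A phase or cycle segment contains no samples."""


class UndefinedVafError(DataError):
    """VAF undefined because the data matrix is identically zero."""


class InvalidOrderError(DataError):
    """Requested factorization order outside the feasible range."""


class AlignmentError(DataError):
    """Muscle orderings of two synergy objects do not agree."""


class DegenerateActivationError(DataError):
    """Activation profile identically zero; timing metrics undefined."""


class UnbalancedDesignError(DataError):
    """A subject is missing a timepoint cell in the repeated-measures design."""
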
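"""Exception hierarchy for the heartage pipeline.

Every stage raises a subclass of :class:`HeartAgeError` so callers (and the
CLI) can map failures to stable exit codes.
"""


class HeartAgeError(Exception):
    """Base class for all heartage-specific errors."""


class MissingLeadError(HeartAgeError):
    """A required ECG lead is absent or leads are in an unusable order."""


class FormatError(HeartAgeError):
    """A file could not be parsed (non-numeric samples, bad header...)."""


class ConfigError(HeartAgeError):
    """Missing or invalid configuration (e.g. unknown sampling rate)."""


class ValidationError(HeartAgeError):
    """A record violates a structural invariant (NaN samples, fs too low)."""


class InsufficientBeatsError(HeartAgeError):
    """Fewer than the minimum number of usable beats were found."""


class FiducialError(HeartAgeError):
    """A landmark (QRS onset/offset, T peak/end) could not be located."""


class DegenerateLoopError(HeartAgeError):
    """A T loop is rank-deficient; eigenvalue ratios are undefined."""


class UndefinedAxisError(HeartAgeError):
    """An axis angle was requested for a (near-)zero vector."""


class IncompleteFeatureError(HeartAgeError):
    """A feature required by the Heart Age model is missing or non-finite."""


class DegenerateFitError(HeartAgeError):
    """A survival fit is impossible (e.g. no events in the cohort)."""


class FitError(HeartAgeError):
    """A survival model failed to converge or lacked support in the data."""
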
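"""Exception and warning hierarchy.

All package errors derive from :class:`AdaptIndexError` so callers can catch
one base class; the CLI maps validation errors to exit code 1 and I/O errors
to exit code 2.
"""


class AdaptIndexError(Exception):
    """Base class for all package errors."""


class DataError(AdaptIndexError):
    """Malformed or non-finite measurement data."""


class InvalidReferenceError(DataError):
    """A pre-load reference value is zero or negative; relative fractions
    are undefined."""


class RecoveryIntervalError(DataError):
    """The recovery value coincides with the post-load value while differing
    from the pre-load value: the recovery fraction diverges.  Indicates a rest
    interval too short to separate the recovery state from the load state."""


class NonApplicableDistributionError(DataError):
    """SD >= mean: the stability coefficient would be non-positive, which the
    model excludes (heavily skewed / Poisson-like baseline distributions)."""


class ConfigError(AdaptIndexError):
    """Invalid analysis or simulation configuration."""


class ValidationError(AdaptIndexError):
    """Profiles or group summaries failed joint validation (e.g. unequal
    homeostatic/adaptive parameter counts between compared units)."""


class LowStabilityWarning(UserWarning):
    """Stability coefficient below 0.5: the baseline distribution is too
    variable for the weighting to be well calibrated."""


class ParadoxicalChangeWarning(UserWarning):
    """The same parameter responds to the load in opposite directions in
    compared units."""


class SlowRecoveryWarning(UserWarning):
    """A recovery fraction exceeds 1: the parameter is further from baseline
    than the size of the recovery step; the rest interval may be too short."""


class RankTieWarning(UserWarning):
    """Two or more groups share an adaptedness value; ranks are dense with
    input-order tie-break."""
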
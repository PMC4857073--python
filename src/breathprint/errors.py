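"""Structured exceptions raised across the package.

Every error carries an actionable message naming the offending field,
(sensor, temperature) pair, row or label, so CLI users never see a bare
stack trace for malformed input.
"""


class BreathprintError(Exception):
    """Base class for all package errors."""


class IncompleteBreathPrintError(BreathprintError):
    """A (sensor, temperature) response is missing from a breath-print."""


class InvalidResponseError(BreathprintError):
    """A sensor response is negative or non-finite."""


class LayoutMismatchError(BreathprintError):
    """Radar layout radius count does not match the response vector."""


class EmptyGroupError(BreathprintError):
    """An aggregate was requested over an empty collection of profiles."""


class DegenerateClassError(BreathprintError):
    """A class has too few members (or only one class is present)."""


class TooManyLatentError(BreathprintError):
    """Requested latent variables exceed min(n_features, n_train - 1)."""


class DimensionMismatchError(BreathprintError):
    """Prediction matrix columns do not match training dimensionality."""


class UndefinedMetricError(BreathprintError):
    """A diagnostic metric has a zero margin in its denominator."""


class SingleClassError(BreathprintError):
    """ROC analysis needs both a positive and a negative class."""


class InfeasibleCutoffError(BreathprintError):
    """No ROC operating point satisfies the requested constraint."""


class InsufficientPairsError(BreathprintError):
    """Fewer than the minimum complete pairs for a correlation."""


class UndefinedCorrelationError(BreathprintError):
    """Rank correlation undefined (zero variance in ranks)."""


class CohortSchemaError(BreathprintError):
    """A cohort file violates the tabular schema."""


class ConfigError(BreathprintError):
    """A generator or CLI configuration is invalid."""


class CalibrationError(BreathprintError):
    """Moment-matching calibration has no valid solution."""
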
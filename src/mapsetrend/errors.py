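"""Exception hierarchy for the mapsetrend package."""


class MapseTrendError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MapseTrendError, ValueError):
    """An invalid configuration value (non-positive rate, probability out of [0, 1], ...)."""


class ValidationError(MapseTrendError, ValueError):
    """A tabular input violates its schema (bad column, unknown vocabulary token, ...)."""


class ContractError(MapseTrendError, RuntimeError):
    """An operation was called on data that violates its precondition."""


class UndefinedRateError(MapseTrendError, ZeroDivisionError):
    """A rate was requested over an empty denominator."""


class UndefinedStatisticError(MapseTrendError, ValueError):
    """A statistic (paired t test, kappa) is undefined for the given data."""


class AdjudicationError(MapseTrendError, ValueError):
    """Observer disagreement cannot be settled because the adjudicator's rating is missing."""
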
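"""Exception hierarchy shared across the package."""


class ImputeBenchError(Exception):
    """Base class for all package errors."""


class ConfigError(ImputeBenchError, ValueError):
    """A configuration field is invalid; the message names the field."""


class InputError(ImputeBenchError, ValueError):
    """Input data violates a precondition (shape, sign, coverage)."""


class NumericError(ImputeBenchError, ArithmeticError):
    """A numeric requirement failed (nonpositive value where a log is taken,
    zero trimmed mean, ...)."""


class AggregationError(ImputeBenchError, ValueError):
    """Rank aggregation over an incomplete or empty group."""
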
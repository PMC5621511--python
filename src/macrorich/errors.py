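"""Exception hierarchy shared across the pipeline stages."""


class MacrorichError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(MacrorichError, ValueError):
    """An argument violates a documented precondition."""


class UndefinedStatisticError(MacrorichError, ValueError):
    """The requested statistic is undefined for this input (e.g. zero variance)."""


class DegenerateWeightsError(MacrorichError, ValueError):
    """A spatial weights matrix cannot be built (e.g. a single valid cell)."""


class EmptyResultError(MacrorichError, ValueError):
    """An operation produced an empty result where content is required."""


class CollinearityError(MacrorichError, ValueError):
    """A regression design matrix is rank deficient."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class OptimizationError(MacrorichError, RuntimeError):
    """A maximum-likelihood optimization failed to converge."""


class SamplingError(MacrorichError, RuntimeError):
    """Endpoint-conditioned path sampling failed after the retry cap."""


class ParseError(MacrorichError, ValueError):
    """A file does not conform to the expected text format."""


class ConfigError(MacrorichError, ValueError):
    """A pipeline configuration is invalid."""
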
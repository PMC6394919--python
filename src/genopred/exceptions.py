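"""Exception hierarchy for genopred."""


class GenopredError(Exception):
    """Base class for all genopred errors."""


class InvalidParameterError(GenopredError, ValueError):
    """A parameter is outside its documented domain."""


class DegenerateArchitectureError(GenopredError, ValueError):
    """Trait architecture yields zero genetic variance where positive variance is required."""


class EmptyPanelError(GenopredError, ValueError):
    """A quality-control step removed every marker or every sample."""


class DegeneratePanelError(GenopredError, ValueError):
    """Genotype panel carries no usable variation (e.g. all-zero coded matrix)."""


class DimensionMismatchError(GenopredError, ValueError):
    """Array shapes are incompatible for the requested operation."""


class RankDeficientDesignError(GenopredError, ValueError):
    """The fixed-effect design matrix is not full column rank."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class UndefinedCorrelationError(GenopredError, ValueError):
    """Pearson correlation is undefined (constant input vector)."""


class McmcDivergenceError(GenopredError, RuntimeError):
    """The MCMC chain produced a non-finite state."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ParseError(GenopredError, ValueError):
    """A data file contains a token outside the allowed alphabet."""


class ConfigError(GenopredError, ValueError):
    """Run configuration is malformed (unknown keys, bad values)."""
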
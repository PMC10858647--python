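"""Exception taxonomy.

``ValidationError`` maps to CLI exit code 1, any other failure to exit code 2.
"""


class GwasPropError(Exception):
    """Base class for all package errors."""


class ValidationError(GwasPropError, ValueError):
    """Invalid parameter or malformed input data."""


class ConvergenceError(GwasPropError, RuntimeError):
    """Iterative solver failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float, n_iter: int):
        super().__init__(message)
        self.residual = residual
        self.n_iter = n_iter


class UndefinedMetricError(GwasPropError, ValueError):
    """A metric is undefined for this query (e.g. no relevant items)."""
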
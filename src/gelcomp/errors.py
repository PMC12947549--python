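"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant (negative
    concentration, non-finite constant, malformed table, ...)."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative solver fails to reach its tolerance.

    The ``residual`` attribute carries the last residual so callers can
    report how far the solve was from closing.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class ParseError(ValueError):
    """Raised on malformed input files; names the offending row/column."""
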
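"""Exception types shared across the pipeline stages."""


class HeatriskError(Exception):
    """Base class for package errors."""


class InvalidInputError(HeatriskError, ValueError):
    """An input value or table violates a documented precondition.

    Carries ``field`` so callers can report which column/argument offended.
    """

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class DataIntegrityError(HeatriskError, ValueError):
    """Structural problem in a table: duplicates, bad joins, span violations."""


class ConvergenceError(HeatriskError, RuntimeError):
    """An iterative solver failed to converge within its iteration cap.

    ``residual`` holds the worst remaining residual at the point of failure.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class SchemaError(HeatriskError, ValueError):
    """A tabular file does not match its documented schema."""
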
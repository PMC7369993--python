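"""Exception hierarchy.

Validation problems (bad files, violated invariants) raise
:class:`ValidationError`; iterative solvers that fail to converge raise
:class:`ConvergenceError` carrying the last iterate.
"""


class FelbindError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FelbindError, ValueError):
    """Invalid input data or configuration."""


class ParseError(ValidationError):
    """Malformed file content; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


class EmptyInputError(ValidationError):
    """A file or sample list contained no usable data."""


class ScheduleError(ValidationError):
    """A lambda schedule is non-contiguous, non-monotone or out of range."""


class ConvergenceError(FelbindError, RuntimeError):
    """An iterative solver exceeded its iteration budget."""

    def __init__(self, message: str, last_value: float | None = None):
        self.last_value = last_value
        super().__init__(message)


class OutOfLandscapeError(FelbindError, LookupError):
    """A collective-variable point fell in an empty/outside bin under policy='error'."""
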
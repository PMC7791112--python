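"""Exception hierarchy shared across the pipeline."""


class PermdegError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(PermdegError, ValueError):
    """A caller-supplied parameter violates its contract."""


class DesignError(ParameterError):
    """The two-group sample design is invalid (missing group, size < 2, ...)."""


class StateError(PermdegError, RuntimeError):
    """An object is in the wrong state for the requested operation
    (e.g. a matrix on the wrong scale, an empty null distribution)."""


class DataError(PermdegError, ValueError):
    """Input values are numerically unusable (non-finite, zeros where a
    log is required, ...)."""


class FormatError(PermdegError, ValueError):
    """A text input file violates its format contract."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
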
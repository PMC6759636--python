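"""Exception taxonomy shared across the package."""


class MotionPrimsError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(MotionPrimsError, ValueError):
    """An argument violates a documented precondition."""


class NumericalError(MotionPrimsError, ArithmeticError):
    """A numerical operation failed (e.g. a singular covariance)."""


class ParseError(MotionPrimsError, ValueError):
    """A file could not be parsed; carries path and line number context."""

    def __init__(self, message: str, path=None, line=None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + where)


class ConfigError(MotionPrimsError, ValueError):
    """A run configuration is malformed or incomplete."""
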
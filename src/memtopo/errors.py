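"""Exception hierarchy shared by all memtopo modules."""


class MemtopoError(Exception):
    """Base class for all toolkit errors."""


class ParseError(MemtopoError):
    """Malformed input file; carries location information when available."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class EmptyInputError(MemtopoError):
    """An input file or corpus contained no usable records."""


class InsufficientAlignmentError(MemtopoError):
    """Alignment depth too small for the requested operation."""


class ConfigError(MemtopoError):
    """Invalid or infeasible configuration value."""


class InputError(MemtopoError):
    """Runtime input violates an operation precondition."""


class TrainingError(MemtopoError):
    """Training corpus cannot support model fitting."""


class UndefinedCorrelationError(MemtopoError):
    """Pearson correlation undefined (constant observed track).

    The mean absolute error is still computed and attached as ``mae``.
    """

    def __init__(self, message: str, mae: float):
        super().__init__(message)
        self.mae = mae
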
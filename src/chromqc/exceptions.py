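"""Exception hierarchy shared across the package."""


class ChromQCError(Exception):
    """Base class for all package errors."""


class ValidationError(ChromQCError, ValueError):
    """Invalid parameter or malformed domain object."""


class ParseError(ChromQCError, ValueError):
    """Malformed input file; carries the file path and line number when known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        if loc:
            message = f"{loc}: {message}"
        super().__init__(message)
        self.path = path
        self.line = line


class NoCoveragePeakError(ChromQCError):
    """Raised when a k-mer histogram has no interior coverage peak."""


class ConfigError(ChromQCError):
    """Invalid pipeline configuration (missing inputs, bad parameters)."""


class StageError(ChromQCError):
    """A pipeline stage failed during execution."""
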
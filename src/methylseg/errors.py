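"""Exception hierarchy shared across the package."""


class MethylsegError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MethylsegError):
    """A file violated the expected dialect; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class AnnotationError(MethylsegError):
    """A gene or interval is inconsistent with the supplied genome."""


class DesignError(MethylsegError):
    """The sample-to-group design is invalid for the requested operation."""


class ConfigError(MethylsegError):
    """A configuration block is missing keys or holds contradictory values."""


class PlacementError(MethylsegError):
    """The genome cannot accommodate the requested planted regions."""


class ConsistencyError(MethylsegError):
    """Inputs that must agree (e.g. a test universe and its member sets) do not."""
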
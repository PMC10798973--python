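"""Exception hierarchy shared across the pipeline stages."""


class ImprintscanError(Exception):
    """Base class for all errors raised by this package."""


class InputError(ImprintscanError):
    """A required input file is missing or unreadable."""


class ParseError(ImprintscanError):
    """A record in an input file violates its format contract.

    Carries the 1-based line number when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ValidationError(ImprintscanError):
    """Structurally well-formed data violates a semantic precondition."""


class ConfigError(ImprintscanError):
    """Invalid pipeline or simulation configuration."""
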
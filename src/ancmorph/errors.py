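"""Exception hierarchy shared across the package."""


class AncmorphError(Exception):
    """Base class for all package-specific errors."""


class SWCParseError(AncmorphError):
    """A line of an SWC file could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class SWCStructureError(AncmorphError):
    """The node table does not form a single rooted tree; names the node."""


class ParameterError(AncmorphError, ValueError):
    """An argument is outside its documented domain."""


class DegenerateInputError(AncmorphError, ValueError):
    """Input is valid but too degenerate for the operation (e.g. root-only trace)."""
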
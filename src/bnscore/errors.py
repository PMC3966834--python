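"""Exception hierarchy shared across the package.

The command-line layer maps these onto distinct exit codes, so library code
raises the most specific class that applies rather than bare ValueError.
"""


class BnScoreError(Exception):
    """Base class for all package errors."""


class ArgumentError(BnScoreError, ValueError):
    """A caller-supplied argument violates a precondition."""


class CapabilityError(BnScoreError):
    """The request is valid but exceeds a deliberate practical bound
    (e.g. exhaustive enumeration beyond n = 5 nodes)."""


class FormatError(BnScoreError):
    """A text input file is malformed. ``line`` is 1-based when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StateError(BnScoreError):
    """An object was used before being put in a valid state."""
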
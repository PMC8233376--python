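"""Exception hierarchy used across the package."""


class ChromacellError(Exception):
    """Base class for all package errors."""


class ParameterError(ChromacellError, ValueError):
    """Invalid argument values (sizes, resolutions, mismatched grids)."""


class FormatError(ChromacellError, ValueError):
    """Malformed input file; message carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DegenerateInputError(ChromacellError, ValueError):
    """Input is structurally valid but degenerate (all-zero matrix, rank < 2)."""


class InsufficientDataError(ChromacellError, ValueError):
    """Not enough observations to carry out the computation."""
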
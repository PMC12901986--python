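"""Exception types shared across the toolkit."""


class CollateralKitError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(CollateralKitError, ValueError):
    """Invalid input values or inconsistent domain objects."""


class FormatError(CollateralKitError, ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class LowCoverageError(CollateralKitError):
    """Transcript does not meet the minimum mean depth for dip detection."""
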
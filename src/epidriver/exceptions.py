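"""Exception hierarchy shared across the pipeline."""


class EpidriverError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EpidriverError):
    """Invalid generator or pipeline configuration."""


class PeakFormatError(EpidriverError):
    """Malformed peak file; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class CollinearityError(EpidriverError):
    """Design matrix is rank deficient; names the offending columns."""

    def __init__(self, message: str, columns: list[str] | None = None):
        self.columns = columns or []
        super().__init__(message)


class IdentificationError(EpidriverError):
    """Instrument does not identify the causal parameter."""


class ValidationError(EpidriverError):
    """Input table fails a structural check."""
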
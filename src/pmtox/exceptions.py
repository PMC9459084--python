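"""Exception hierarchy for the pmtox pipeline."""


class PmtoxError(Exception):
    """Base class for all pmtox errors."""


class FormatError(PmtoxError):
    """A delimited-text input does not match the expected layout."""


class DataValidationError(PmtoxError):
    """Input values violate a declared support (e.g. negative peak area)."""


class ConfigError(PmtoxError):
    """A configuration value is outside its allowed range."""


class JoinError(PmtoxError):
    """Batch identifiers do not line up between two tables."""

    def __init__(self, message, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)


class TransformError(PmtoxError):
    """A dimensionless / normalization transform is undefined for the input."""


class FitError(PmtoxError):
    """A model fit failed to converge or is ill-posed."""
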
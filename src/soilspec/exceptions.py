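"""Exception hierarchy shared across the package."""


class SoilSpecError(Exception):
    """Base class for all package errors."""


class FormatError(SoilSpecError, ValueError):
    """A file or table does not conform to the expected layout."""


class ValidationError(SoilSpecError, ValueError):
    """Data violates a container invariant (duplicate IDs, NaNs, ...)."""


class ConfigurationError(SoilSpecError, ValueError):
    """A parameter combination is inadmissible."""


class CorrectionError(SoilSpecError, ValueError):
    """A per-sample correction (e.g. MSC) could not be applied.

    Carries the offending sample ID so callers can report it.
    """

    def __init__(self, message: str, sample_id: str | None = None):
        super().__init__(message)
        self.sample_id = sample_id
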
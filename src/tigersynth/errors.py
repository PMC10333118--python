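"""Exception taxonomy shared across the package."""


class TigersynthError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TigersynthError, ValueError):
    """A file does not conform to the documented CSV schema."""


class ValidationError(TigersynthError, ValueError):
    """A dataset violates a documented invariant (names the offender)."""


class ConsistencyError(ValidationError):
    """Cross-table inconsistency, e.g. a reserve missing from covariates."""


class ConfigError(TigersynthError, ValueError):
    """An invalid configuration value."""


class InsufficientDonorsError(TigersynthError, ValueError):
    """Too few donor reserves for the requested operation."""


class FitError(TigersynthError, RuntimeError):
    """The synthetic-control optimisation failed; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
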
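"""Exception hierarchy for the bsdr package."""


class BSDRError(Exception):
    """Base class for all bsdr errors."""


class ConfigurationError(BSDRError):
    """A user-supplied configuration value is invalid or inconsistent."""


class DataValidationError(BSDRError):
    """Input data violate a structural requirement (shape, dtype, labels)."""


class ParseError(DataValidationError):
    """A delimited table could not be parsed into a spectral dataset."""


class DomainError(BSDRError):
    """A normalized band index lies outside the closed unit interval."""


class TrainingDivergenceError(BSDRError):
    """The training loss became non-finite."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite training loss at epoch {epoch}")


class StratificationError(BSDRError):
    """A class is missing from a split that must contain every class."""


class CombinatorialGuardError(BSDRError):
    """An exhaustive search was refused because the subset count is too large."""
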
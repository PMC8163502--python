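"""Exception hierarchy shared across the pipeline stages."""


class AnesRecovError(Exception):
    """Base class for all package errors."""


class FormatError(AnesRecovError):
    """Unreadable or unrecognized input file."""


class MontageError(AnesRecovError):
    """Missing or unrecognizable EEG channels."""


class SamplingError(AnesRecovError):
    """Sampling rate cannot support the requested analysis band."""


class ReferenceError_(AnesRecovError):
    """Mastoid (or substitute) reference channels unavailable."""


class EpochUnavailableError(AnesRecovError):
    """A requested state epoch cannot be cut without touching masked data."""

    def __init__(self, state: str, reason: str = ""):
        self.state = state
        self.reason = reason
        super().__init__(f"epoch {state!r} unavailable: {reason}")


class ParameterError(AnesRecovError):
    """Invalid analysis parameter."""


class LengthError(AnesRecovError):
    """Input series too short for the requested embedding/window."""


class StandardizationError(AnesRecovError):
    """Baseline sessions required for standardization are missing."""


class FitQualityError(AnesRecovError):
    """MCMC or REML fit failed convergence diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class DesignError(AnesRecovError):
    """Degenerate design matrix (empty cells, constant input, rank loss)."""


class DataError(AnesRecovError):
    """Physically impossible input data (e.g. negative activity counts)."""


class ConstantInputError(AnesRecovError):
    """Correlation undefined because one variable is constant."""
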
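"""Exception hierarchy.

All package-specific failures derive from :class:`SabrekinError` so that
callers (and the CLI) can distinguish validation problems from genuine bugs.
"""


class SabrekinError(Exception):
    """Base class for all package errors."""


class DomainError(SabrekinError, ValueError):
    """An argument is outside its physically meaningful domain."""


class InfeasibleSystemError(SabrekinError):
    """The mass-balance / equilibrium system has no non-negative root."""


class UndefinedRatioError(SabrekinError):
    """Pool ratio requested for a system with no bound-substrate pool."""


class ConfigurationError(SabrekinError):
    """Inconsistent or incomplete model configuration."""


class SaturationError(SabrekinError):
    """EXSY integrals are outside the invertible range (mixing time too long)."""


class InsufficientDataError(SabrekinError):
    """Too few data points for the requested estimate."""


class SchemaError(SabrekinError):
    """A data table does not conform to the expected dialect."""


class UnconvergedFitError(SabrekinError):
    """Optimizer failed to converge; carries the best-so-far result."""

    def __init__(self, message, result=None):
        super().__init__(message)
        self.result = result
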
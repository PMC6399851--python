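"""Exception hierarchy for the simulation package."""


class BystanderTGIError(Exception):
    """Base class for all package-specific errors."""


class InvalidStateError(BystanderTGIError):
    """A model state violates its invariants (non-finite, negative, ...)."""


class IntegrationError(BystanderTGIError):
    """An ODE or quadrature solve failed; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class GridError(BystanderTGIError):
    """A time grid does not satisfy the requirements of an operation."""


class ConfigError(BystanderTGIError):
    """A scenario configuration failed validation."""
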
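"""Exception hierarchy for mrkit.

All package errors derive from :class:`MRKitError` so callers can catch one
type at a pipeline boundary while tests assert specific subclasses.
"""


class MRKitError(Exception):
    """Base class for all mrkit errors."""


class ConfigError(MRKitError):
    """Invalid configuration: missing column mapping, bad parameter, etc."""


class EmptyInputError(MRKitError):
    """An operation received no usable rows/instruments."""


class HarmonizationError(MRKitError):
    """Exposure/outcome tables cannot be harmonized (e.g. duplicate ids)."""


class EstimationError(MRKitError):
    """An estimator received degenerate input (k too small, beta_x = 0...)."""


class ConvergenceError(EstimationError):
    """An iterative estimator failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
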
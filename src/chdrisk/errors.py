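"""Exception hierarchy shared across the package."""


class ChdRiskError(Exception):
    """Base class for all package errors."""


class ValidationError(ChdRiskError, ValueError):
    """Input violates a documented contract (bad value, mismatched IDs, ...)."""


class PanelFormatError(ChdRiskError, ValueError):
    """A panel or coefficient file does not have the documented layout."""


class CovariateRangeError(ValidationError):
    """A risk-factor value falls outside the model's defined covariate range."""
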
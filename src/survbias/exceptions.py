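"""Exception types shared across the package."""


class SurvbiasError(Exception):
    """Base class for all package-specific errors."""


class CalibrationError(SurvbiasError):
    """Raised when the outcome-intercept root-finding cannot bracket a solution."""


class ConfigurationError(SurvbiasError):
    """Raised for invalid perturbation / run configurations."""


class UndefinedMetricError(SurvbiasError):
    """Raised when a metric is undefined for the given inputs (e.g. single-class AUC)."""
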
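"""Exception hierarchy shared across the pipeline."""


class HypoburdenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HypoburdenError):
    """A configuration value is missing, malformed, or inconsistent."""


class DataError(HypoburdenError):
    """An input record violates the schema or a physiologic/logical constraint."""


class SeparationError(HypoburdenError):
    """Logistic fit failed because the outcome is (quasi-)separable."""


class UndefinedEstimateError(HypoburdenError):
    """An estimand is undefined for the given data (e.g. interval with n=0)."""
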
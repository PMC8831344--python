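"""Exception types shared across the package."""


class NoduleVarError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(NoduleVarError):
    """A tabular input is missing or has misnamed required columns."""


class ValidationError(NoduleVarError, ValueError):
    """A record violates a data invariant (e.g. non-positive volume)."""


class InsufficientDataError(NoduleVarError, ValueError):
    """Too few observations for the requested statistic."""


class DegenerateDesignError(NoduleVarError, ValueError):
    """A regression design matrix has no variation in the predictor."""


class ThresholdNeverReachedError(NoduleVarError, ValueError):
    """A non-growing nodule below the intervention threshold never crosses it."""
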
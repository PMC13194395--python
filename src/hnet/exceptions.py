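"""Package-specific exception hierarchy."""


class HNetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HNetError):
    """A declared column, option or spec field is missing or inconsistent."""


class DataError(HNetError):
    """Input data violates a dataset invariant (non-numeric, non-finite...)."""


class ShapeError(HNetError):
    """Array dimensions do not match a model or spec contract."""


class TrainingError(HNetError):
    """Optimization diverged or could not be run."""


class EvaluationError(HNetError):
    """A metric was requested without the inputs it needs (e.g. no oracle)."""


class ExtrapolationWarning(UserWarning):
    """A dose grid extends beyond the treatment support seen at fit time."""
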
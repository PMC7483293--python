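"""Exception hierarchy for ppiscale."""


class PpiScaleError(Exception):
    """Base class for all ppiscale errors."""


class InsufficientDataError(PpiScaleError):
    """Too few observations for the requested computation."""


class DegenerateBaselineError(PpiScaleError):
    """Session baseline signal has zero variance; z-scoring undefined."""


class InvalidNormalizerError(PpiScaleError):
    """Normalization requested with a non-positive standard deviation."""


class UndefinedRatioError(PpiScaleError):
    """PPI ratio requested with zero baseline movement."""


class InsufficientDesignError(PpiScaleError):
    """Stimulus design too sparse to identify the startle curve."""


class SpecError(PpiScaleError):
    """Invalid synthetic cohort specification."""


class PpiScaleWarning(UserWarning):
    """Base warning category for ppiscale."""
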
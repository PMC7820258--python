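"""Exception hierarchy shared across the toolkit.

Every error raised on bad user input derives from :class:`StressError`
so callers can catch one type at tool boundaries.
"""


class StressError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(StressError):
    """A table is missing required columns or has a malformed header."""


class ValidationError(StressError):
    """Row-level contract violation (duplicate IDs, bad probabilities, ...)."""


class DanglingReferenceError(StressError):
    """A record references an image_id absent from the manifest."""


class AlignmentError(StressError):
    """Ensemble members (or paired sets) do not cover identical keys."""


class ContractError(StressError):
    """A black-box predictor or input violated its declared contract."""


class DegenerateInputError(StressError):
    """A metric is undefined on this input (e.g. single-class AUROC)."""


class InsufficientDataError(StressError):
    """Too few observations to run the requested statistical test."""
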
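"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`EDRComplexError` so callers (and the
CLI) can attribute a failure to a stage without string matching.
"""


class EDRComplexError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(EDRComplexError, ValueError):
    """A parameter is outside its documented range."""


class NoPeaksError(EDRComplexError):
    """R-peak detection found nothing usable (e.g. flat signal)."""


class TooCorruptedError(EDRComplexError):
    """Ectopic correction flagged essentially every beat."""


class TooShortError(EDRComplexError):
    """Record (or series) is too short for the requested operation."""


class DegenerateSeriesError(EDRComplexError):
    """A statistic is undefined on this input (e.g. zero-variance series)."""


class CalibrationError(EDRComplexError):
    """A requested complexity target is outside the attainable range."""


class SchemaError(EDRComplexError, ValueError):
    """A cohort table or config file violates the documented schema."""
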
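"""Exception hierarchy for the AIIA pipeline.

All package-specific errors derive from :class:`AIIAError` so callers can
catch pipeline failures without masking programming errors.
"""


class AIIAError(Exception):
    """Base class for all AIIA-specific errors."""


class ParameterError(AIIAError, ValueError):
    """An argument is outside its documented domain."""


class ParseError(AIIAError, ValueError):
    """A text input could not be parsed; the message names the line."""


class TooShortRecordError(AIIAError, ValueError):
    """An RR record has fewer than two intervals, so no difference exists."""


class ValidationError(AIIAError, ValueError):
    """A domain invariant is violated (e.g. a non-positive interval)."""


class InfeasibleKError(ParameterError):
    """Requested more clusters than there are distinct values to cluster."""


class AlphabetOverflowError(ParameterError):
    """More than 26 clusters requested; the symbol alphabet is a-z."""


class AlphabetMismatchError(AIIAError, ValueError):
    """A symbol sequence contains letters outside the vocabulary's alphabet."""


class ShapeError(AIIAError, ValueError):
    """Feature vectors with inconsistent vocabularies were combined."""


class DegenerateModelError(AIIAError, ValueError):
    """A classifier was fitted on data that cannot support a model."""


class UndefinedClassError(AIIAError, ValueError):
    """A per-class statistic was requested for a class with no members."""
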
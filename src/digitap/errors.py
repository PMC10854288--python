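"""Exception hierarchy.

Every malformed input raises a typed error; no operation returns a
partially-constructed object.
"""


class DigitapError(Exception):
    """Base class for all package errors."""


class TraceFormatError(DigitapError):
    """Trace file cannot be parsed (missing columns, bad header)."""


class TraceValidationError(DigitapError):
    """Parsed trace violates an invariant (non-monotone time, negative
    displacement, unequal lever lengths, ...)."""


class ParameterError(DigitapError):
    """Invalid configuration or simulation parameters."""


class ReferenceError_(DigitapError):
    """Normative reference missing, degenerate (zero SD), or queried for
    an unknown metric."""


class ScoringError(DigitapError):
    """A score cannot be computed (e.g. a required metric is absent)."""


class ClassifierError(DigitapError):
    """An external per-strike tremor predictor failed."""


class InsufficientPerformanceError(DigitapError):
    """Too few voluntary strikes to compute metrics (the redo case)."""
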
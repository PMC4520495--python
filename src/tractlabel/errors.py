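"""Exception hierarchy.

Validation problems (bad arguments, inconsistent shapes, degenerate inputs)
all derive from :class:`ValidationError`; file-format problems derive from
:class:`FormatError`.  The CLI maps these to exit codes 1 and 2.
"""


class TractLabelError(Exception):
    """Base class for all package errors."""


class ValidationError(TractLabelError):
    """Invalid argument values, shapes, or preconditions."""


class DegenerateInputError(ValidationError):
    """Geometric input too degenerate to process (e.g. < 2 distinct points)."""


class InsufficientDataError(ValidationError):
    """Not enough samples for the requested estimator."""


class UndefinedMetricError(ValidationError):
    """A performance metric's denominator is empty/degenerate."""


class ConfigurationError(ValidationError):
    """A parameter combination leaves the algorithm without a valid state."""


class FormatError(TractLabelError):
    """Malformed or unsupported file content."""
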
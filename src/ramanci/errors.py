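"""Exception hierarchy.

All package errors derive from :class:`RamanCIError` so callers can catch
one base class. Data-shape problems raise :class:`ValidationError`; values
outside an axis span raise :class:`RangeError`; mathematically degenerate
inputs (zero variance, zero denominator) raise
:class:`DegenerateInputError`.
"""


class RamanCIError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(RamanCIError):
    """A text file could not be parsed (message names the offending line)."""


class FormatError(RamanCIError):
    """A structured file (e.g. JCAMP-DX) violates its format contract."""


class ValidationError(RamanCIError):
    """Input data violate a documented precondition or invariant."""


class RangeError(RamanCIError):
    """A requested coordinate lies outside the data's axis span."""


class DegenerateInputError(RamanCIError):
    """Input is mathematically degenerate for the requested operation."""


class ConvergenceError(RamanCIError):
    """An iterative algorithm failed to converge."""


class FitError(RamanCIError):
    """A model fit is impossible (rank-deficient or degenerate design)."""


class MetricError(RamanCIError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class ConfigError(RamanCIError):
    """A workflow configuration is inconsistent or references missing data."""
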
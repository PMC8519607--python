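"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`TeanetError`,
so callers can catch one type at a pipeline boundary.
"""


class TeanetError(Exception):
    """Base class for all errors raised by teanet."""


class ValidationError(TeanetError):
    """A container invariant is violated (non-positive intensity, bad flag...)."""


class FormatError(TeanetError):
    """A delimited text file cannot be interpreted (duplicate ids, bad header)."""


class ConfigError(TeanetError):
    """A run-configuration document is malformed or contains unknown keys."""


class ParameterError(TeanetError, ValueError):
    """An argument is outside its admissible set."""


class DomainError(TeanetError, ValueError):
    """A numeric input is outside the mathematical domain of an operation."""


class InsufficientDataError(TeanetError):
    """Too few samples/values to compute the requested statistic."""


class AlignmentError(TeanetError):
    """Two tables that must share samples have an empty or too-small overlap."""


class StructuralError(TeanetError):
    """A pair set or network does not have the required structure."""
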
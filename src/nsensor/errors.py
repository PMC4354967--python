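"""Exception hierarchy shared across the package.

All domain errors derive from :class:`NSensorError` so callers can catch
one base class; each subclass also derives from the closest builtin
(``ValueError`` for bad inputs) to stay friendly to generic handling.
"""


class NSensorError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(NSensorError, ValueError):
    """An input violates a documented precondition or invariant."""


class UndefinedInputError(ValidationError):
    """A quantity is mathematically undefined for the given input."""


class RankDeficiencyError(ValidationError):
    """Too few distinct abscissae to identify the regression model."""


class NonConcaveError(ValidationError):
    """A quadratic response is not concave (a2 >= 0), so it cannot be
    inverted for an N recommendation."""


class DerivationError(ValidationError):
    """The parametric algorithm cannot be derived from the supplied
    calibration coefficients."""


class EmptyReferenceError(ValidationError):
    """No plots qualify as the well-fertilized reference."""
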
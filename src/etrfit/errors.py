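"""Exception hierarchy shared across the package."""


class EtrfitError(Exception):
    """Base class for all etrfit errors."""


class FormatError(EtrfitError):
    """A required column or structural element is missing from an input file."""


class ParseError(EtrfitError):
    """A cell in an input file could not be converted to a number."""


class ValidationError(EtrfitError):
    """Input data violate a structural invariant (duplicates, too short, ...)."""


class DomainError(EtrfitError, ValueError):
    """A numeric argument is outside the physically meaningful domain."""


class NoMaximumError(EtrfitError):
    """The response curve is monotone (beta = 0): no interior maximum exists."""


class UnderdeterminedError(ValidationError):
    """Fewer observations than free parameters + 1."""


class UndefinedRSquaredError(EtrfitError):
    """R^2 is undefined because the total sum of squares is zero."""
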
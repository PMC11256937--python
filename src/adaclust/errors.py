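"""Exception hierarchy used across the package."""


class AdaclustError(Exception):
    """Base class for package errors."""


class InputError(AdaclustError):
    """A file or argument the caller supplied is missing or unusable."""


class ValidationError(AdaclustError, ValueError):
    """Data violates a structural invariant (negative counts, shape mismatch, ...)."""


class DomainError(AdaclustError, ValueError):
    """A numeric argument lies outside the mathematical domain of an operation."""


class NumericalError(AdaclustError, ArithmeticError):
    """A computation produced non-finite values."""
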
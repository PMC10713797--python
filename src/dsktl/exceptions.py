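"""Exception types shared across the package."""


class DSKTLError(Exception):
    """Base class for all package errors."""


class InvalidInputError(DSKTLError, ValueError):
    """Raised when an input violates a documented precondition."""


class NotPositiveDefiniteError(DSKTLError, ValueError):
    """Raised when a matrix required to be SPD is singular or indefinite."""
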
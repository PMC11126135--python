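"""Exception hierarchy shared across the package.

The split mirrors how failures should be handled: ``UsageError`` means the
caller passed arguments that can never make sense (fix the call site),
``DataError`` means the input data violate a precondition (inspect the
data), and ``DomainError`` means a physical quantity left its admissible
range (e.g. a non-positive relaxation time).
"""


class IvimFieldError(Exception):
    """Base class for all errors raised by this package."""


class UsageError(IvimFieldError, ValueError):
    """The requested operation was called with invalid arguments."""


class DataError(IvimFieldError, ValueError):
    """Input data violate a precondition of the operation."""


class DomainError(IvimFieldError, ValueError):
    """A physical parameter lies outside its admissible domain."""


class ExtrapolationWarning(UserWarning):
    """A fitted model is being evaluated outside its calibrated range."""
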
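"""Exception hierarchy for idpchain.

All validation failures raise subclasses of :class:`IdpChainError`, which is
itself a ``ValueError`` so callers can catch either level.
"""


class IdpChainError(ValueError):
    """Base class for all idpchain errors."""


class FormatError(IdpChainError):
    """A file or table violates its format contract."""


class EmptyInputError(IdpChainError):
    """An input contains no usable records."""


class FitError(IdpChainError):
    """A fit is undefined or degenerate for the given input."""
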
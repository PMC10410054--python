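"""Exception types shared across the package."""


class RegclockError(Exception):
    """Base class for all package errors."""


class ParseError(RegclockError, ValueError):
    """A file or identifier could not be parsed."""


class ValidationError(RegclockError, ValueError):
    """An input violated a documented precondition or invariant."""
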
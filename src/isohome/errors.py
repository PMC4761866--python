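"""Exception hierarchy shared across the package."""


class IsohomeError(Exception):
    """Base class for all package errors."""


class ParseError(IsohomeError):
    """A text input (coefficient table, config) could not be parsed."""


class ValidationError(IsohomeError):
    """Inputs violate a documented precondition or invariant."""


class DomainError(IsohomeError):
    """A query falls outside the valid domain (time span, grid hull...)."""


class IsolineNotFoundError(IsohomeError):
    """No contour at the requested level exists within the search window."""
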
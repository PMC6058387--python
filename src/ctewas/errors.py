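"""Exception hierarchy.

Every contract violation raises a distinct subclass of :class:`CtEwasError`
so callers (and tests) can discriminate bad file layout from out-of-range
values from misuse of an API.
"""


class CtEwasError(Exception):
    """Base class for all errors raised by ctewas."""


class FormatError(CtEwasError):
    """A table does not have the required layout (columns, ids)."""


class DuplicateIDError(FormatError):
    """Probe or sample identifiers are not unique."""


class ParseError(FormatError):
    """A cell could not be parsed; message carries row/column context."""


class ValidationError(CtEwasError):
    """Values violate a domain invariant (range, consistency)."""


class ValueRangeError(ValidationError):
    """A numeric value lies outside its admissible range."""


class CategoryError(ValidationError):
    """A categorical token is not among the accepted levels."""


class ContractError(CtEwasError):
    """An operation was called with inputs violating its precondition."""


class ConfigError(CtEwasError):
    """Invalid configuration or design parameters."""
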
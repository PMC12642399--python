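"""Exception types shared across the package."""


class PhaselinkError(Exception):
    """Base class for all package errors."""


class DomainError(PhaselinkError, ValueError):
    """An input is outside the physically or mathematically admissible domain."""


class ValidationError(PhaselinkError, ValueError):
    """A structural contract on the inputs is violated (shapes, ordering, labels)."""


class ParseError(PhaselinkError, ValueError):
    """A delimited text file could not be interpreted as the expected table."""
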
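"""Exception hierarchy shared across the package."""


class NBSBMError(Exception):
    """Base class for package errors."""


class ValidationError(NBSBMError, ValueError):
    """An input violates a documented precondition."""


class ParseError(NBSBMError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class CapacityError(NBSBMError, RuntimeError):
    """A brute-force routine was asked to exceed its enumeration guard."""
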
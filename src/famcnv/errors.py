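"""Exception types shared across the package."""


class FamCnvError(Exception):
    """Base class for all famcnv errors."""


class ParseError(FamCnvError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(FamCnvError):
    """Parsed content violates a domain invariant."""
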
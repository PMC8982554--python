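"""Exception types shared across the package."""


class EnhancerLinkError(ValueError):
    """Base class for all package-raised errors."""


class ParseError(EnhancerLinkError):
    """An input file could not be parsed; the message names the offending line."""


class ValidationError(EnhancerLinkError):
    """An input or argument violates a documented invariant."""
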
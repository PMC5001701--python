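"""Exception types shared across loaders and the statistics engine."""


class MirpathError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MirpathError, ValueError):
    """A malformed record in an input file; the message names the line."""


class ValidationError(MirpathError, ValueError):
    """Structurally valid input that violates a domain invariant."""
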
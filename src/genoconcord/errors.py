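"""Exception types: parse failures vs semantic validation failures."""


class GenoConcordError(Exception):
    """Base class for all package errors."""


class ParseError(GenoConcordError):
    """A file could not be parsed into the data model."""


class ValidationError(GenoConcordError):
    """Parsed data violate a documented invariant."""
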
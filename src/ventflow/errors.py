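"""Exception hierarchy shared across the pipeline."""


class VentflowError(Exception):
    """Base class for all package errors."""


class FormatError(VentflowError):
    """A file could not be parsed (malformed header, bad newick, ...)."""


class ValidationError(VentflowError):
    """Parsed content violates a domain invariant (negative count, duplicate id, ...)."""


class ConfigurationError(VentflowError):
    """The requested analysis cannot be set up (missing off-axis sample, bad weights, ...)."""
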
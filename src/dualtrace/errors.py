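"""Exception types raised by the pipeline."""


class DualtraceError(ValueError):
    """Base class for all errors raised by this package."""


class FormatError(DualtraceError):
    """A file could not be parsed (bad header, non-numeric intensity, ...)."""


class ValidationError(DualtraceError):
    """Parsed content violates a domain invariant (negative intensity,
    duplicate feature id, unknown sample, ...)."""


class DesignError(DualtraceError):
    """The sample design cannot support the requested operation (missing
    isotope arm, too few replicates, ...)."""
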
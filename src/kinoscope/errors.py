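"""Exception hierarchy shared across the pipeline."""


class KinoscopeError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(KinoscopeError):
    """A file is structurally malformed (bad header, duplicate coordinates, ...)."""


class ValidationError(KinoscopeError):
    """Inputs parse but violate a cross-object invariant."""


class ParameterError(KinoscopeError):
    """A user-supplied parameter is outside its documented range."""
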
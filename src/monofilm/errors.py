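"""Exception hierarchy shared across the package."""


class MonofilmError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MonofilmError):
    """A file could not be parsed as an isotherm."""


class InsufficientDataError(MonofilmError):
    """Too few data points survive to support the requested operation."""


class ValidationError(MonofilmError):
    """Inputs violate a documented invariant (metadata, config, study set)."""


class DomainError(MonofilmError):
    """A request lies outside the physically meaningful domain."""
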
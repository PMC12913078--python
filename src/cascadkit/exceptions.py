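"""Exception hierarchy shared across cascadkit."""


class CascadkitError(Exception):
    """Base class for all cascadkit errors."""


class ValidationError(CascadkitError):
    """Raised when input data violates its documented schema or range."""


class ConfigurationError(CascadkitError):
    """Raised when a required configuration object is missing or inconsistent."""


class GenerationError(CascadkitError):
    """Raised when a synthetic-data specification is infeasible."""
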
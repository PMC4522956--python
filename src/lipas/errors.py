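"""Exception hierarchy shared across the suite."""


class LipasError(Exception):
    """Base class for all validated-input and configuration failures."""


class ValidationError(LipasError, ValueError):
    """Raised when user-supplied data violate a documented precondition."""


class ConfigurationError(LipasError, RuntimeError):
    """Raised when a model/topology combination is internally inconsistent."""
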
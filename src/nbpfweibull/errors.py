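"""Exception hierarchy shared across the package."""


class NBPFError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(NBPFError, ValueError):
    """A distribution parameter is outside its domain (must be positive and finite)."""


class DomainError(NBPFError, ValueError):
    """A function argument (probability, count, grid value) is outside its domain."""


class DataValidationError(NBPFError, ValueError):
    """Observed data violate the model's support (nonpositive, nonfinite, missing)."""


class NumericalError(NBPFError, RuntimeError):
    """A numerical routine failed to converge or overflowed."""


class ConfigurationError(NBPFError, ValueError):
    """An unknown model identifier, dataset id, or option value was supplied."""
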
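"""Exception types shared across the package."""


class FinescaleError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FinescaleError):
    """A prior, model or analysis configuration is invalid or unresolvable."""


class ValidationError(FinescaleError):
    """Input data violate a documented precondition."""


class PhasingError(FinescaleError):
    """Phased haplotypes were requested from unphased genotype data."""
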
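"""Exception hierarchy shared across the package."""


class DissimscaleError(Exception):
    """Base class for all package-specific errors."""


class DataFormatError(DissimscaleError):
    """A file could not be parsed into the expected structure."""


class DataValidationError(DissimscaleError):
    """Parsed data violate a contract (duplicate keys, negative cover, ...)."""


class DegenerateInputError(DissimscaleError):
    """Input is structurally valid but the requested quantity is undefined
    (zero-variance trait, empty community, star phylogeny, ...)."""


class LayoutError(DissimscaleError):
    """Survey-design geometry is internally inconsistent."""


class ConfigError(DissimscaleError):
    """A run configuration is invalid or ambiguous."""


class ConvergenceError(DissimscaleError):
    """A model fit failed to converge; carries the optimizer diagnostics."""
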
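"""Exception hierarchy shared across the package."""


class DisfcError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DisfcError):
    """Invalid configuration value; message names the offending field."""


class SchemaError(DisfcError):
    """Tabular input does not match the expected schema."""


class DimensionError(DisfcError):
    """Array shapes incompatible with the requested operation."""


class DegenerateInputError(DisfcError):
    """Input is degenerate for the operation (e.g. constant volume)."""


class FormatError(DisfcError):
    """A file could not be parsed in its declared format."""
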
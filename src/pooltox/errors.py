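"""Exception types shared across the package."""


class PooltoxError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PooltoxError):
    """A file did not follow its declared dialect (carries line context)."""


class SchemaError(PooltoxError):
    """A table was structurally valid but missing required columns/libraries."""


class ValidationError(PooltoxError, ValueError):
    """Arguments violated a documented precondition."""


class ConfigError(PooltoxError):
    """A pipeline configuration was invalid (unknown key, missing path)."""
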
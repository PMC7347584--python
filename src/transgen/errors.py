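"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A configuration object or file is invalid."""


class DesignError(ValueError):
    """The data do not support the requested comparison (e.g. empty group)."""


class FitError(RuntimeError):
    """Model fitting failed (e.g. no residual degrees of freedom)."""


class SchemaError(ValueError):
    """A table violates its declared schema."""
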
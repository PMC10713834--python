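"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An invalid simulation or analysis configuration."""


class DegenerateInputError(ValueError):
    """Input without enough variation to support the requested computation."""


class GeometryError(ValueError):
    """Volumes whose shapes or affines do not match."""
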
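"""Exception hierarchy shared across the pipeline stages."""


class RgcPipeError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(RgcPipeError, ValueError):
    """Invalid configuration (counts, fractions, thresholds)."""


class GenerationError(RgcPipeError, RuntimeError):
    """Synthetic-data generation failed (negative rates, non-invertible warp)."""


class SchemaError(RgcPipeError, ValueError):
    """A file does not conform to the expected on-disk layout."""
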
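"""Exception hierarchy shared across the pipeline."""


class RehoscopeError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(RehoscopeError, ValueError):
    """Image dimensionality, shape, or affine mismatch."""


class ConfigError(RehoscopeError, ValueError):
    """Invalid or missing configuration value."""


class DesignError(RehoscopeError, ValueError):
    """Statistical design is rank-deficient or otherwise unusable."""


class DegenerateDataError(RehoscopeError, ValueError):
    """Input data carry no usable variance for the requested statistic."""


class PipelineError(RehoscopeError, RuntimeError):
    """A pipeline stage could not run to completion."""
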
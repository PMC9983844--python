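"""Exception types shared across the package."""


class ResonetError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ResonetError, ValueError):
    """A constructor or sampler parameter is outside its valid range."""


class ShapeError(ResonetError, ValueError):
    """Array arguments have incompatible lengths or shapes."""


class UndefinedStatisticError(ResonetError, ValueError):
    """A requested statistic is undefined for the given data (e.g. zero variance)."""


class ConfigError(ResonetError, ValueError):
    """A run configuration is malformed: unknown key or out-of-range value."""
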
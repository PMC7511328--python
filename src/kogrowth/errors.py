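"""Exception hierarchy shared across the package."""


class KogrowthError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(KogrowthError):
    """Invalid configuration value or combination."""


class PlacementError(KogrowthError):
    """Synthetic gene placement impossible for the requested density."""


class CalibrationError(KogrowthError):
    """Target correlation unreachable; message names the feasible range."""


class EstimationError(KogrowthError):
    """Growth-rate estimation impossible on the given curve."""


class UndefinedStatisticError(KogrowthError):
    """A statistic is undefined on the given input (constant vector, empty set...)."""


class DataFormatError(KogrowthError):
    """A file or table violates the expected layout."""
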
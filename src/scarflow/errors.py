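"""Exception hierarchy shared by all scarflow modules."""


class ScarflowError(Exception):
    """Base class for all scarflow errors."""


class InvalidGeometryError(ScarflowError, ValueError):
    """Channel geometry violates a physical invariant (non-positive dimension, R <= w/2, ...)."""


class NumericConfigurationError(ScarflowError, ValueError):
    """A numeric scheme was configured so that it cannot converge (too few series terms, ...)."""


class OutOfDomainError(ScarflowError, ValueError):
    """A lateral position is outside the admissible range for a finite-size particle."""


class ModelConfigurationError(ScarflowError, ValueError):
    """A force model is degenerate (no equilibrium exists, all coefficients zero, ...)."""


class CalibrationError(ScarflowError, ValueError):
    """Calibration input is unusable (under-determined table, missing columns, ...)."""


class LayoutError(ScarflowError, ValueError):
    """Requested cell density cannot be placed without violating the overlap constraint."""


class ConfigError(ScarflowError, ValueError):
    """A configuration file or block failed validation; message names the offending key."""


class UnsupportedFormatError(ScarflowError, ValueError):
    """An image file is not an 8/16-bit grayscale TIFF stack."""


class UndefinedMetricError(ScarflowError, ValueError):
    """A requested metric is undefined on this input (empty port, empty table, ...)."""
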
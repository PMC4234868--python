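"""Exception hierarchy shared across the package."""


class PedprobeError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PedprobeError, ValueError):
    """A numeric parameter violates its physical or geometric constraint."""


class InsufficientDataError(PedprobeError, ValueError):
    """Too few observations to compute the requested statistic."""


class DegenerateProfileError(PedprobeError, ValueError):
    """A depth profile cannot be normalized (zero/negative first point)."""


class NoOnsetError(PedprobeError, ValueError):
    """No persistent deviation beyond the flat region was found."""


class GridMismatchError(PedprobeError, ValueError):
    """Spectra do not share a common wavelength grid."""


class RangeError(PedprobeError, ValueError):
    """Requested wavelength window not covered by the spectrum grid."""


class CalibrationError(PedprobeError, ValueError):
    """Synthetic template could not be calibrated to its factor targets."""


class IncompleteLabelingError(PedprobeError, ValueError):
    """A labeled series is missing one of the required tissue regions."""


class DegenerateBandError(PedprobeError, ValueError):
    """Alarm band has coincident or inverted endpoints."""


class ConfigError(PedprobeError, ValueError):
    """Configuration file failed to parse or validate."""


class DependencyError(PedprobeError, RuntimeError):
    """A pipeline stage is missing an upstream artifact."""
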
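"""Exception hierarchy for the carostiff pipeline."""


class CarostiffError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CarostiffError):
    """Invalid simulation or pipeline configuration."""


class SimulationError(CarostiffError):
    """Unphysiologic or impossible state requested from a generator."""


class DetectionError(CarostiffError):
    """Fewer than two qualifying wall echoes in a frame (reposition probe)."""


class TrackLossError(CarostiffError):
    """Echo tracker lost both lock and recovery margin."""


class GeometryError(CarostiffError):
    """Wall geometry implies a non-positive lumen diameter."""


class QualityError(CarostiffError):
    """No beat of acceptable quality; measurement must be repeated."""


class PressureError(CarostiffError):
    """Pressure pair violates Ps > Pd > 0."""


class StrainError(CarostiffError):
    """Degenerate diameter strain (Ds <= Dd or out of physiologic range)."""


class UndefinedRDError(CarostiffError):
    """Relative difference of a pair whose mean is exactly zero."""


class MissingDataError(CarostiffError):
    """A required covariate is absent; subject excluded from the analysis."""


class ValidationError(CarostiffError):
    """Contradictory or out-of-coding questionnaire / model inputs."""


class SingularFitError(CarostiffError):
    """Regression design matrix is (numerically) rank deficient."""
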
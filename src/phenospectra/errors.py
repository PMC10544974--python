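"""Exception hierarchy.

Every error raised on a contract violation derives from
:class:`PhenospectraError` so callers can catch package failures narrowly.
"""


class PhenospectraError(Exception):
    """Base class for all package errors."""


class DesignError(PhenospectraError):
    """Invalid field-trial design request (e.g. indivisible block size)."""


class ParameterError(PhenospectraError):
    """Simulation parameter outside its admissible range."""


class SchedulingError(PhenospectraError):
    """Observation requested outside the sensor's collection window."""


class LayoutError(PhenospectraError):
    """Invalid field layout (e.g. overlapping plot polygons)."""


class CalibrationError(PhenospectraError):
    """Empirical-line calibration cannot be fit (degenerate panel readings)."""


class BandMismatchError(PhenospectraError):
    """A band required by an operation is absent from the input."""


class CoverageError(PhenospectraError):
    """Spectral curve does not cover the wavelength range an operation needs."""


class DegenerateGroupError(PhenospectraError):
    """A normalization group has zero spread; carries the group label."""


class ExtractionError(PhenospectraError):
    """Zonal extraction failed for a plot (polygon outside the raster)."""


class RegressionError(PhenospectraError):
    """Ordinary least squares cannot be fit (zero predictor variance, n < 3)."""


class ConvergenceError(PhenospectraError):
    """Iterative variance-component fit failed to converge; carries a trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class UndefinedHeritabilityError(PhenospectraError):
    """All variance components are zero; heritability is undefined."""


class ValidationError(PhenospectraError):
    """Pipeline configuration or table schema violation; names the field."""
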
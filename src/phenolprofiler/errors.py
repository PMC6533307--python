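"""Exception hierarchy shared across the pipeline stages."""


class PhenolProfilerError(Exception):
    """Base class for all package-specific errors."""


class InvalidFactorError(PhenolProfilerError):
    """A factor specification or design parameter is unusable (e.g. step <= 0)."""


class InvalidRegionError(PhenolProfilerError):
    """The optimization region is unbounded or empty."""


class SingularDesignError(PhenolProfilerError):
    """The design matrix is rank deficient; the quadratic cannot be fitted."""


class IncompleteDesignError(PhenolProfilerError):
    """One or more design points lack a measured response."""


class MalformedTreeError(PhenolProfilerError):
    """A spectral tree violates structural invariants (e.g. child mz >= parent mz)."""


class DuplicatePeakError(PhenolProfilerError):
    """Two spectral trees in one batch share a peak id."""


class InsufficientCalibrationError(PhenolProfilerError):
    """Too few calibration points, or no spread in concentration."""


class InvalidCurveError(PhenolProfilerError):
    """A calibration curve has a non-positive or zero slope where one is required."""


class InvalidMeasurementError(PhenolProfilerError):
    """A peak area or concentration that must be positive is not."""


class InvalidRecoveryError(PhenolProfilerError):
    """Recovery rate outside (0, 1.2] supplied to quantification."""


class InvalidSpikeError(PhenolProfilerError):
    """Spiked amount in a recovery experiment must be positive."""


class UndefinedRSDError(PhenolProfilerError):
    """Relative standard deviation is undefined (mean zero or < 2 values)."""


class ParseError(PhenolProfilerError):
    """A data file could not be parsed; the message names the offending record."""
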
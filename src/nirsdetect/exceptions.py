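"""Exception hierarchy for the nirsdetect pipeline."""


class NirsdetectError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NirsdetectError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DataError(NirsdetectError, ValueError):
    """Malformed or inconsistent input data (scan, labels, montage)."""


class NumericalError(NirsdetectError, ArithmeticError):
    """A numerically singular or ill-posed system (e.g. extinction matrix)."""


class TrainingError(NirsdetectError, RuntimeError):
    """Model fitting failed (single-class input, non-convergence)."""


class CalibrationError(NirsdetectError, RuntimeError):
    """Probability calibration could not be fitted."""


class PipelineError(NirsdetectError, RuntimeError):
    """A degenerate pipeline state (e.g. an empty impaired class)."""


class LeakageError(NirsdetectError, RuntimeError):
    """Participant-level train/test contamination detected by the audit."""
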
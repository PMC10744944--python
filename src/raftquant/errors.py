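"""Exception hierarchy shared across the pipeline."""


class RaftquantError(Exception):
    """Base class for all package errors."""


class ValidationError(RaftquantError, ValueError):
    """A value or container violates its documented invariants."""


class CoverageError(ValidationError):
    """A spectral grid does not cover the wavelengths the analysis needs."""


class UsageError(RaftquantError, ValueError):
    """An operation was called with arguments outside its contract."""


class RangeError(RaftquantError, ValueError):
    """A scalar argument lies outside its admissible range."""


class DegenerateDataError(RaftquantError, ValueError):
    """Input carries no usable signal (flat series, zero bands, zero baseline)."""


class CalibrationError(RaftquantError, ValueError):
    """A quenching calibration is internally inconsistent."""


class FitError(RaftquantError, RuntimeError):
    """A least-squares fit failed to converge or produced unphysical parameters."""
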
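"""Exception hierarchy for fetalwave."""


class FetalwaveError(Exception):
    """Base class for all fetalwave errors."""


class InvalidArgumentError(FetalwaveError, ValueError):
    """A function argument violates its contract (non-finite, wrong range...)."""


class DegenerateKernelError(FetalwaveError, ValueError):
    """A raw wavelet profile is identically zero and cannot be normalized."""


class UnknownBankError(FetalwaveError, KeyError):
    """Requested wavelet bank name is not registered."""


class InvalidSignalError(FetalwaveError, ValueError):
    """A Signal violates its invariants (fs <= 0, too short, non-finite)."""


class LevelOverflowError(FetalwaveError, ValueError):
    """Requested decomposition depth exceeds what the signal length allows."""


class LevelRangeError(FetalwaveError, IndexError):
    """Level index outside the decomposition's computed range."""


class CalibrationError(FetalwaveError, ArithmeticError):
    """Frame calibration failed (kernel with negligible response at a level)."""


class ZeroEnergyError(FetalwaveError, ValueError):
    """Signal or decomposition carries no energy; probabilities undefined."""


class InvalidBandError(FetalwaveError, ValueError):
    """Band-pass edges are outside (0, Nyquist) or inverted."""


class InvalidAnnotationError(FetalwaveError, ValueError):
    """Annotation list is unsorted, negative, or otherwise malformed."""


class UndefinedMetricsError(FetalwaveError, ValueError):
    """All peak counts are zero; detector metrics are undefined."""


class RecordFormatError(FetalwaveError, ValueError):
    """A recording file cannot be parsed (ragged rows, unknown fs...)."""
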
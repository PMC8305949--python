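"""Uniformly sampled real-valued signals.

The carrier type for abdominal, maternal and fetal ECG traces.  Amplitudes
are conventionally in mV but nothing downstream depends on the unit; all
detector thresholds are relative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSignalError

__all__ = ["Signal"]


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled time series.

    Parameters
    ----------
    samples : array-like of float
        Amplitudes, finite, length >= 2.
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float, default 0.0
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    _skip_validation: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self._skip_validation:
            return
        if samples.ndim != 1:
            raise InvalidSignalError("signal samples must be one-dimensional")
        if samples.size < 2:
            raise InvalidSignalError("signal needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise InvalidSignalError("signal samples must be finite")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise InvalidSignalError(f"sampling rate must be > 0, got {self.fs}")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record duration in seconds (n / fs)."""
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(len(self)) / self.fs

    def with_samples(self, samples: np.ndarray) -> "Signal":
        """Return a new Signal sharing fs and t0 with replaced samples."""
        return Signal(np.asarray(samples, dtype=float), self.fs, self.t0)
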
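"""R-peak detection, tolerance matching, and detector scoring.

Detection thresholds are relative to a robust maximum (99th percentile of
|signal|), so scoring is invariant under amplitude scaling; candidate
peaks closer than a refractory interval are pruned keeping the larger
amplitude (the RR-interval false-peak rule).  Detections are matched to
reference annotations one-to-one by greedy nearest-time pairing inside a
tolerance window (default +/-20 ms, suited to fetal heart rates; the
+/-150 ms standard window is available through ``tol_s``).

Scored quantities (all on the percent scale except FHR):

    FHR      = detections / duration * 60          [bpm]
    Accuracy = TD / (TD + FP + FN) * 100
    PPV      = TD / (TD + FP) * 100
    Se       = TD / (TD + FN) * 100
    F1       = 2 * PPV * Se / (PPV + Se)

with TD the truly diagnosed (matched) peaks, FP the unmatched detections
and FN the missed references.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    InvalidAnnotationError,
    InvalidArgumentError,
    UndefinedMetricsError,
)
from .signal import Signal

__all__ = [
    "PeakList",
    "MatchResult",
    "MetricsReport",
    "detect_peaks",
    "match_peaks",
    "fhr",
    "metrics",
]

#: fetal refractory default: 240 bpm physiological ceiling
DEFAULT_MIN_RR_S = 0.25
#: maternal refractory default (150 bpm ceiling)
MATERNAL_MIN_RR_S = 0.4
#: acceptance window between detection and nearest reference
DEFAULT_TOL_S = 0.020


@dataclass(frozen=True)
class PeakList:
    """Strictly increasing peak times in seconds."""

    times: np.ndarray
    source: str = "detected"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float).ravel()
        object.__setattr__(self, "times", times)
        if times.size and not np.all(np.diff(times) > 0):
            raise InvalidAnnotationError("peak times must be strictly increasing")
        if times.size and (times < 0).any():
            raise InvalidAnnotationError("peak times must be non-negative")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class MatchResult:
    """Tolerance-matching outcome between detections and references."""

    TD: int
    FP: int
    FN: int
    tol_s: float
    pairs: Tuple[Tuple[int, int], ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class MetricsReport:
    """Detector scores on the percent scale plus the heart rate in bpm."""

    fhr: float
    accuracy: float
    ppv: float
    se: float
    f1: float

    def to_dict(self) -> dict:
        return {
            "fhr_bpm": self.fhr,
            "accuracy_pct": self.accuracy,
            "ppv_pct": self.ppv,
            "se_pct": self.se,
            "f1": self.f1,
        }


def detect_peaks(
    signal: Signal,
    threshold_frac: float = 0.5,
    min_rr_s: float = DEFAULT_MIN_RR_S,
) -> PeakList:
    """Detect R-peaks as thresholded local maxima of |signal|.

    Candidates are local maxima of the rectified signal exceeding
    ``threshold_frac`` times the robust maximum (99th percentile of
    |signal|); candidates closer than ``min_rr_s`` are pruned keeping the
    larger amplitude.  A flat signal yields an empty list.
    """
    if not (0.0 < threshold_frac < 1.0):
        raise InvalidArgumentError("threshold_frac must lie in (0, 1)")
    if min_rr_s <= 0.0:
        raise InvalidArgumentError("min_rr_s must be positive")
    x = np.abs(signal.samples)
    robust_max = float(np.percentile(x, 99))
    if robust_max <= 0.0:
        # sparser than 1% nonzero: fall back to the true maximum so
        # isolated spikes on a silent baseline are still found
        robust_max = float(x.max())
    if robust_max <= 0.0:
        return PeakList(np.empty(0), source="detected")
    distance = max(1, int(round(min_rr_s * signal.fs)))
    # find_peaks' distance pruning keeps the higher peak, which is exactly
    # the RR-interval rule
    idx, _ = find_peaks(x, height=threshold_frac * robust_max, distance=distance)
    return PeakList(signal.t0 + idx / signal.fs, source="detected")


def match_peaks(
    detected: PeakList, reference: PeakList, tol_s: float = DEFAULT_TOL_S
) -> MatchResult:
    """Greedy nearest-time one-to-one matching within +/- tol_s.

    Candidate (reference, detection) pairs inside the window are accepted
    in order of increasing time difference (ties broken toward the earlier
    reference, then the earlier detection); each side is matched at most
    once.  Unmatched detections count as FP, unmatched references as FN.
    """
    if tol_s <= 0.0:
        raise InvalidArgumentError("tol_s must be positive")
    det, ref = detected.times, reference.times
    cand: List[Tuple[float, int, int]] = []
    lo = 0
    for i, r in enumerate(ref):
        while lo < det.size and det[lo] < r - tol_s:
            lo += 1
        k = lo
        while k < det.size and det[k] <= r + tol_s:
            cand.append((abs(det[k] - r), i, k))
            k += 1
    cand.sort()
    used_ref = np.zeros(ref.size, dtype=bool)
    used_det = np.zeros(det.size, dtype=bool)
    pairs: List[Tuple[int, int]] = []
    for _, i, k in cand:
        if not used_ref[i] and not used_det[k]:
            used_ref[i] = used_det[k] = True
            pairs.append((i, k))
    td = len(pairs)
    return MatchResult(
        TD=td,
        FP=int(det.size) - td,
        FN=int(ref.size) - td,
        tol_s=tol_s,
        pairs=tuple(sorted(pairs)),
    )


def fhr(peaks: PeakList, duration_s: float) -> float:
    """Heart rate in bpm: detected peak count over duration, times 60."""
    if duration_s <= 0.0:
        raise InvalidArgumentError("duration must be positive")
    return len(peaks) / duration_s * 60.0


def metrics(match: MatchResult, duration_s: float | None = None) -> MetricsReport:
    """Accuracy, PPV, Se and F1 (percent scale) from match counts.

    With TD = 0 but detections or references present, all scores are 0
    and the undefined F1 is reported as 0 with a warning.  ``duration_s``
    additionally yields the detected-peak rate as FHR (0 when omitted).
    """
    td, fp, fn = match.TD, match.FP, match.FN
    if td + fp + fn == 0:
        raise UndefinedMetricsError("no peaks in either list; metrics undefined")
    accuracy = td / (td + fp + fn) * 100.0
    ppv = td / (td + fp) * 100.0 if td + fp else 0.0
    se = td / (td + fn) * 100.0 if td + fn else 0.0
    if ppv + se > 0.0:
        f1 = 2.0 * ppv * se / (ppv + se)
    else:
        warnings.warn(
            "F1 undefined (PPV = Se = 0); reporting 0", RuntimeWarning, stacklevel=2
        )
        f1 = 0.0
    rate = (td + fp) / duration_s * 60.0 if duration_s else 0.0
    return MetricsReport(fhr=rate, accuracy=accuracy, ppv=ppv, se=se, f1=f1)
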
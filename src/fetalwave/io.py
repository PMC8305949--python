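"""Readers and writers for recordings, annotations and metric reports.

Formats
-------
* DAISY-style plain text: a whitespace-separated numeric matrix, one row
  per sample; an optional first time column is auto-detected by strict
  monotonicity.  Without a time column the sampling rate must be given.
* CSV records: header ``time_s,abd[,mecg,fecg]``.
* PhysioNet records through the optional ``wfdb`` dependency.
* Annotation CSV: header ``time_s,label``; sample-index annotations are
  converted with an explicit sampling rate.
* Metric reports as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InvalidAnnotationError, RecordFormatError
from .peaks import MetricsReport, PeakList
from .signal import Signal
from .synth import SyntheticRecord

__all__ = [
    "RecordSource",
    "read_record",
    "read_annotations",
    "write_annotations",
    "write_record",
    "write_report",
]


@dataclass(frozen=True)
class RecordSource:
    """Where and how to read one channel of a recording."""

    path: str
    format: str = "daisy_text"
    channel: int = 0
    fs_override: Optional[float] = None

    def __post_init__(self) -> None:
        if self.format not in ("daisy_text", "wfdb", "csv"):
            raise RecordFormatError(f"unknown format {self.format!r}")


def _load_text_matrix(path: Path) -> np.ndarray:
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or line.lstrip().startswith("#"):
                continue
            try:
                row = [float(p) for p in parts]
            except ValueError as exc:
                raise RecordFormatError(
                    f"{path}: non-numeric value on line {lineno}"
                ) from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise RecordFormatError(
                    f"{path}: ragged row on line {lineno} "
                    f"({len(row)} values, expected {width})"
                )
            rows.append(row)
    if not rows:
        raise RecordFormatError(f"{path}: no numeric rows")
    return np.asarray(rows)


def _has_time_column(mat: np.ndarray) -> bool:
    if mat.shape[1] < 2 or mat.shape[0] < 3:
        return False
    t = mat[:, 0]
    dt = np.diff(t)
    return bool(np.all(dt > 0) and np.allclose(dt, dt.mean(), rtol=1e-3))


def read_record(source: RecordSource) -> Signal:
    """Read one channel of a recording as a Signal.

    The sampling rate comes from the file's time column or header, or from
    ``fs_override``; a DAISY-style file without a time column requires it.
    """
    path = Path(source.path)
    if not path.exists():
        raise FileNotFoundError(f"record file not found: {path}")
    if source.format == "daisy_text":
        mat = _load_text_matrix(path)
        if _has_time_column(mat):
            t = mat[:, 0]
            data = mat[:, 1:]
            fs = source.fs_override or 1.0 / float(np.mean(np.diff(t)))
            t0 = float(t[0])
        else:
            data = mat
            if source.fs_override is None:
                raise RecordFormatError(
                    f"{path}: no time column; a sampling rate is required"
                )
            fs, t0 = source.fs_override, 0.0
        if not (0 <= source.channel < data.shape[1]):
            raise RecordFormatError(
                f"channel {source.channel} out of range (file has {data.shape[1]})"
            )
        return Signal(data[:, source.channel], fs, t0)
    if source.format == "csv":
        frame = pd.read_csv(path)
        value_cols = [c for c in frame.columns if c != "time_s"]
        if "time_s" not in frame.columns or not value_cols:
            raise RecordFormatError(f"{path}: need columns time_s and a channel")
        if not (0 <= source.channel < len(value_cols)):
            raise RecordFormatError(
                f"channel {source.channel} out of range (columns: {value_cols})"
            )
        t = frame["time_s"].to_numpy(dtype=float)
        fs = source.fs_override or 1.0 / float(np.mean(np.diff(t)))
        return Signal(frame[value_cols[source.channel]].to_numpy(dtype=float), fs, float(t[0]))
    # wfdb
    try:
        import wfdb
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise RecordFormatError(
            "reading PhysioNet records requires the optional 'wfdb' package"
        ) from exc
    rec = wfdb.rdrecord(str(path))  # pragma: no cover - optional dependency
    if not (0 <= source.channel < rec.p_signal.shape[1]):  # pragma: no cover
        raise RecordFormatError(f"channel {source.channel} out of range")
    return Signal(  # pragma: no cover
        rec.p_signal[:, source.channel], float(rec.fs), 0.0
    )


def write_record(record: SyntheticRecord, path) -> None:
    """Write a synthetic record as CSV (time_s, abd, mecg, fecg)."""
    pd.DataFrame(
        {
            "time_s": record.abd.times,
            "abd": record.abd.samples,
            "mecg": record.mecg_clean.samples,
            "fecg": record.fecg_clean.samples,
        }
    ).to_csv(path, index=False, float_format="%.9g")


def write_annotations(peaks: PeakList, path) -> None:
    """Write peak times as annotation CSV (time_s, label)."""
    pd.DataFrame({"time_s": peaks.times, "label": peaks.source}).to_csv(
        path, index=False, float_format="%.9f"
    )


def read_annotations(path, fs: Optional[float] = None) -> PeakList:
    """Read annotation CSV; ``fs`` converts sample-index annotations.

    Accepts either a ``time_s`` column or (with ``fs``) a ``sample``
    column; times must be non-negative and strictly increasing.
    """
    frame = pd.read_csv(path)
    if "time_s" in frame.columns:
        times = frame["time_s"].to_numpy(dtype=float)
    elif "sample" in frame.columns:
        if fs is None:
            raise InvalidAnnotationError(
                "sample-index annotations need a sampling rate (fs)"
            )
        times = frame["sample"].to_numpy(dtype=float) / fs
    else:
        raise InvalidAnnotationError(f"{path}: need a time_s or sample column")
    label = str(frame["label"].iloc[0]) if "label" in frame.columns and len(frame) else "reference"
    return PeakList(times, source=label)


def write_report(report: MetricsReport, path) -> None:
    """Write a metrics report as JSON."""
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")
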
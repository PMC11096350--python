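"""Core record containers and readers/writers for RR-interval and ECG files.

Units convention used throughout the package: RR intervals in milliseconds,
beat times (and every other duration) in seconds, sampling rates in Hz,
heart rate in beats per minute.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "SampledSignal",
    "RriSeries",
    "CohortManifest",
    "read_rri",
    "write_rri",
    "read_ecg_csv",
    "read_cohort_manifest",
    "FLAG_NORMAL",
    "FLAG_ECTOPIC",
    "FLAG_INTERPOLATED",
]

FLAG_NORMAL = "normal"
FLAG_ECTOPIC = "ectopic"
FLAG_INTERPOLATED = "interpolated"
_VALID_FLAGS = {FLAG_NORMAL, FLAG_ECTOPIC, FLAG_INTERPOLATED}

GROUP_DCSSC = "dcSSc"
GROUP_LCSSC = "lcSSc"
_GROUP_ALIASES = {"dcssc": GROUP_DCSSC, "lcssc": GROUP_LCSSC}


@dataclass
class SampledSignal:
    """Uniformly sampled waveform (raw ECG, or the 4 Hz resampled RRI series).

    Parameters
    ----------
    values : array-like
        Sample amplitudes (arbitrary units for ECG, ms for resampled RRI).
    fs : float
        Sampling rate in Hz, strictly positive.
    start_time : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValidationError("SampledSignal requires a non-empty 1-D array")
        if not np.isfinite(self.values).all():
            raise ValidationError("SampledSignal contains NaN/inf values")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration(self) -> float:
        """Span covered by the samples, in seconds."""
        return (self.values.size - 1) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.fs


@dataclass
class RriSeries:
    """Beat-to-beat RR intervals with beat timestamps and quality flags.

    ``intervals[k]`` is the RR interval (ms) ending at ``beat_times[k]`` (s),
    so ``beat_times[k] - beat_times[k-1] == intervals[k] / 1000``.
    """

    intervals: np.ndarray
    beat_times: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.flags is None:
            self.flags = np.full(self.intervals.size, FLAG_NORMAL, dtype=object)
        else:
            self.flags = np.asarray(self.flags, dtype=object)
        if self.intervals.size == 0:
            raise ValidationError("RriSeries requires at least one interval")
        if not (self.intervals > 0).all():
            raise ValidationError("all RR intervals must be strictly positive")
        if self.beat_times.size != self.intervals.size or self.flags.size != self.intervals.size:
            raise ValidationError("intervals, beat_times and flags must have equal length")
        if self.beat_times.size > 1:
            dt = np.diff(self.beat_times)
            if not (dt > 0).all():
                raise ValidationError("beat_times must be strictly increasing")
            if not np.allclose(dt, self.intervals[1:] / 1000.0, rtol=0, atol=1e-9):
                raise ValidationError("beat_times inconsistent with intervals")
        bad = set(self.flags) - _VALID_FLAGS
        if bad:
            raise ValidationError(f"unknown beat flags: {sorted(bad)}")

    @classmethod
    def from_intervals(cls, intervals: Sequence[float], t0: float = 0.0,
                       flags: Sequence[str] | None = None) -> "RriSeries":
        """Build a series from intervals only; beat times by cumulative sum."""
        iv = np.asarray(intervals, dtype=float)
        times = t0 + np.cumsum(iv) / 1000.0
        return cls(iv, times, None if flags is None else np.asarray(flags, dtype=object))

    @property
    def n_beats(self) -> int:
        return int(self.intervals.size)

    @property
    def duration(self) -> float:
        """Time from first to last beat, seconds."""
        return float(self.beat_times[-1] - self.beat_times[0])


@dataclass
class CohortManifest:
    """Cohort listing: one row per subject with group label and segment paths."""

    rows: pd.DataFrame

    REQUIRED = ("subject_id", "group", "path_S1", "path_S2", "input_kind")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        ids = self.rows["subject_id"].astype(str)
        dup = ids[ids.duplicated()].tolist()
        if dup:
            raise ValidationError(f"duplicate subject_id values: {sorted(set(dup))}")
        groups = self.rows["group"].astype(str).str.lower()
        unknown = sorted(set(groups) - set(_GROUP_ALIASES))
        if unknown:
            raise ValidationError(f"unknown group labels: {unknown}")
        self.rows = self.rows.copy()
        self.rows["group"] = groups.map(_GROUP_ALIASES)
        kinds = set(self.rows["input_kind"].astype(str))
        bad = kinds - {"ecg", "rri"}
        if bad:
            raise ValidationError(f"unknown input_kind values: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.rows)


def _parse_float(token: str, path, lineno: int) -> float:
    try:
        v = float(token)
    except ValueError:
        raise ParseError(f"{path}: non-numeric value {token!r} on line {lineno}") from None
    if not np.isfinite(v) or v <= 0:
        raise ParseError(f"{path}: non-positive interval {token!r} on line {lineno}")
    return v


def read_rri(path, dialect: Literal["plain_ms", "csv_times"] = "plain_ms") -> RriSeries:
    """Read an RR-interval file.

    ``plain_ms``: one interval in ms per line; beat times are reconstructed
    by cumulative sum. ``csv_times``: CSV with columns ``beat_time_s,rr_ms``
    and an optional ``flag`` column.
    """
    path = Path(path)
    text = path.read_text()
    if dialect == "plain_ms":
        intervals = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            intervals.append(_parse_float(line, path, lineno))
        if not intervals:
            raise ParseError(f"{path}: empty RRI file")
        return RriSeries.from_intervals(intervals)
    if dialect == "csv_times":
        reader = csv.DictReader(io.StringIO(text))
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty RRI file")
        for col in ("beat_time_s", "rr_ms"):
            if col not in reader.fieldnames:
                raise ParseError(f"{path}: missing column {col!r}")
        times, intervals, flags = [], [], []
        for lineno, row in enumerate(reader, start=2):
            intervals.append(_parse_float(row["rr_ms"], path, lineno))
            try:
                times.append(float(row["beat_time_s"]))
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric beat_time_s on line {lineno}") from None
            flags.append(row.get("flag") or FLAG_NORMAL)
        if not intervals:
            raise ParseError(f"{path}: empty RRI file")
        return RriSeries(np.array(intervals), np.array(times), np.array(flags, dtype=object))
    raise ValidationError(f"unknown dialect {dialect!r}")


def write_rri(series: RriSeries, path, dialect: Literal["plain_ms", "csv_times"] = "plain_ms") -> None:
    """Write an RriSeries; 3-decimal fixed point so round-trips are lossless."""
    path = Path(path)
    if dialect == "plain_ms":
        path.write_text("".join(f"{v:.3f}\n" for v in series.intervals))
    elif dialect == "csv_times":
        lines = ["beat_time_s,rr_ms,flag\n"]
        for t, v, f in zip(series.beat_times, series.intervals, series.flags):
            lines.append(f"{t:.6f},{v:.3f},{f}\n")
        path.write_text("".join(lines))
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")


def read_ecg_csv(path, fs: float | None = None) -> SampledSignal:
    """Read an ECG CSV with columns ``time_s,amplitude``.

    The sampling rate is inferred from the median time step unless given.
    """
    df = pd.read_csv(path)
    for col in ("time_s", "amplitude"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if df["amplitude"].isna().any():
        raise ParseError(f"{path}: NaN amplitude values")
    t = df["time_s"].to_numpy(dtype=float)
    if fs is None:
        if t.size < 2:
            raise ParseError(f"{path}: cannot infer fs from fewer than 2 samples")
        fs = 1.0 / float(np.median(np.diff(t)))
    return SampledSignal(df["amplitude"].to_numpy(dtype=float), fs=fs, start_time=float(t[0]))


def read_cohort_manifest(path) -> CohortManifest:
    """Read and validate a cohort manifest CSV (see CohortManifest.REQUIRED)."""
    df = pd.read_csv(path, dtype=str)
    if "input_kind" not in df.columns:
        df["input_kind"] = "rri"
    return CohortManifest(df)
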
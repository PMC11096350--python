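"""Artifact correction, detrending, 4 Hz spline resampling, segment extraction.

Ectopic/artifact rule: a beat whose interval deviates more than a fractional
threshold (default 30%) from the running median of an 11-beat window is
removed and replaced by cubic-spline interpolation over the surrounding good
beats. Beat times are rebuilt by cumulative sum so series invariants hold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter

from .errors import CoverageError, InsufficientDataError, QualityError, ValidationError
from .signal_io import FLAG_INTERPOLATED, FLAG_NORMAL, RriSeries, SampledSignal

__all__ = [
    "SegmentSpec",
    "CorrectionReport",
    "correct_artifacts",
    "detrend_poly",
    "resample_spline",
    "extract_segment",
]

#: stand-up noise guard before the orthostatism segment, seconds
STANDUP_GUARD_S = 10.0


@dataclass
class SegmentSpec:
    """One 5-min analysis window of the stand-up protocol."""

    phase: Literal["S1_decubitus", "S2_orthostatism"]
    start: float
    duration: float = 300.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError("segment duration must be positive")
        if self.start < 0:
            raise ValidationError("segment start must be >= 0")


@dataclass
class CorrectionReport:
    n_flagged: int
    n_interpolated: int
    fraction_edited: float


def correct_artifacts(rri: RriSeries, dev_threshold: float = 0.3,
                      window: int = 11, max_fraction: float = 0.2) -> tuple[RriSeries, CorrectionReport]:
    """Flag and spline-interpolate beats deviating from the running median.

    Raises QualityError when more than ``max_fraction`` of beats are flagged
    (the segment should be rejected rather than repaired).
    """
    n = rri.n_beats
    if n < window:
        raise InsufficientDataError(f"need at least {window} beats, got {n}")
    iv = rri.intervals
    med = median_filter(iv, size=window, mode="nearest")
    bad = np.abs(iv - med) > dev_threshold * med
    n_flagged = int(bad.sum())
    frac = n_flagged / n
    if frac > max_fraction:
        raise QualityError(
            f"{n_flagged}/{n} beats ({100 * frac:.1f}%) flagged; segment should be rejected")
    if n_flagged == 0:
        return rri, CorrectionReport(0, 0, 0.0)
    good = ~bad
    # interpolate interval value at the flagged beats' original times
    spline = CubicSpline(rri.beat_times[good], iv[good])
    new_iv = iv.copy()
    new_iv[bad] = spline(rri.beat_times[bad])
    new_iv = np.clip(new_iv, 1e-3, None)
    flags = rri.flags.copy()
    flags[bad] = FLAG_INTERPOLATED
    t0 = rri.beat_times[0] - iv[0] / 1000.0
    corrected = RriSeries.from_intervals(new_iv, t0=t0, flags=flags)
    return corrected, CorrectionReport(n_flagged, n_flagged, frac)


def detrend_poly(sig: SampledSignal, order: int = 3) -> SampledSignal:
    """Residual of a least-squares polynomial fit of the given order."""
    if order < 0:
        raise ValidationError("polynomial order must be >= 0")
    n = sig.values.size
    if n <= order + 1:
        raise InsufficientDataError(f"need more than {order + 1} samples, got {n}")
    t = np.linspace(-1.0, 1.0, n)  # normalized abscissa for conditioning
    coeffs = np.polynomial.polynomial.polyfit(t, sig.values, order)
    residual = sig.values - np.polynomial.polynomial.polyval(t, coeffs)
    return SampledSignal(residual, fs=sig.fs, start_time=sig.start_time)


def resample_spline(rri: RriSeries, fs_out: float = 4.0) -> SampledSignal:
    """Cubic-spline resample (beat_time, interval) onto a uniform grid.

    Produces the equidistant series x(i) used by spectral analysis.
    """
    if rri.n_beats < 4:
        raise InsufficientDataError("need at least 4 beats for cubic resampling")
    t, v = rri.beat_times, rri.intervals
    spline = CubicSpline(t, v)
    n_out = int(np.floor((t[-1] - t[0]) * fs_out)) + 1
    grid = t[0] + np.arange(n_out) / fs_out
    return SampledSignal(spline(grid), fs=fs_out, start_time=float(t[0]))


def extract_segment(rri: RriSeries, spec: SegmentSpec) -> RriSeries:
    """Beats in the half-open window [start, start+duration), re-offset to 0."""
    end = spec.start + spec.duration
    # allow up to two missing seconds at the tail (last beat rarely lands on
    # the exact window edge)
    if rri.beat_times[-1] + 2.0 < end:
        raise CoverageError(
            f"window [{spec.start}, {end}) s not covered; recording spans "
            f"[{rri.beat_times[0]:.1f}, {rri.beat_times[-1]:.1f}] s")
    mask = (rri.beat_times >= spec.start) & (rri.beat_times < end)
    if mask.sum() < 2:
        raise InsufficientDataError("fewer than 2 beats in window")
    return RriSeries(rri.intervals[mask], rri.beat_times[mask] - spec.start,
                     rri.flags[mask])
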
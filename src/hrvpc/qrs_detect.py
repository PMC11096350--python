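"""Pan–Tompkins R-wave detection: ECG trace -> RR-interval series.

Classic stages: zero-phase band-pass (5–15 Hz), derivative, squaring,
moving-window integration (150 ms), adaptive dual thresholds with a 200 ms
refractory period. Peak times are refined to the raw-signal argmax in a
±50 ms window around the integrated-signal trigger so RR intervals are not
biased by filter delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError, NoBeatsError, ValidationError
from .signal_io import RriSeries, SampledSignal

__all__ = ["QrsConfig", "detect_r_peaks", "ecg_to_rri"]


@dataclass
class QrsConfig:
    """Detector constants (conventional Pan–Tompkins defaults)."""

    bandpass_lo: float = 5.0
    bandpass_hi: float = 15.0
    integration_window: float = 0.150  # s
    refractory: float = 0.200  # s
    threshold_decay: float = 0.125  # running-estimate update fraction
    refine_window: float = 0.050  # s, raw-signal argmax search half-width

    def validate(self, fs: float) -> None:
        if not (0 < self.bandpass_lo < self.bandpass_hi < fs / 2):
            raise ValidationError(
                f"band-pass {self.bandpass_lo}-{self.bandpass_hi} Hz invalid for fs={fs}")
        if self.refractory <= 0:
            raise ValidationError("refractory must be positive")


def _integrated_envelope(ecg: SampledSignal, cfg: QrsConfig) -> np.ndarray:
    fs = ecg.fs
    sos = sps.butter(2, [cfg.bandpass_lo, cfg.bandpass_hi], btype="band", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, ecg.values)
    deriv = np.gradient(filtered) * fs
    squared = deriv ** 2
    win = max(1, int(round(cfg.integration_window * fs)))
    return sps.convolve(squared, np.ones(win) / win, mode="same")


def detect_r_peaks(ecg: SampledSignal, cfg: QrsConfig | None = None) -> np.ndarray:
    """Return strictly increasing R-peak times in seconds.

    Raises NoBeatsError on a flat trace and ValidationError for fs < 100 Hz
    or recordings shorter than 10 s.
    """
    cfg = cfg or QrsConfig()
    if ecg.fs < 100:
        raise ValidationError(f"sampling rate {ecg.fs} Hz unsupported (need >= 100 Hz)")
    if ecg.duration < 10:
        raise InsufficientDataError("ECG shorter than 10 s")
    cfg.validate(ecg.fs)
    if np.ptp(ecg.values) == 0:
        raise NoBeatsError("flat ECG trace: no beats detectable")

    fs = ecg.fs
    env = _integrated_envelope(ecg, cfg)
    refractory_n = max(1, int(round(cfg.refractory * fs)))

    # candidate local maxima of the envelope, refractory-spaced
    cand, _ = sps.find_peaks(env, distance=refractory_n)
    if cand.size == 0:
        raise NoBeatsError("no candidate peaks in integrated signal")

    # adaptive dual-threshold classification (signal vs noise running
    # levels); offline initialization from global envelope statistics so a
    # quiet lead-in cannot collapse the thresholds
    spki = float(np.percentile(env[cand], 90)) * 0.5
    npki = float(env.mean()) * 0.5
    decay = cfg.threshold_decay
    accepted: list[int] = []
    for idx in cand:
        thresh = npki + 0.25 * (spki - npki)
        if env[idx] > thresh:
            accepted.append(idx)
            spki = decay * env[idx] + (1 - decay) * spki
        else:
            npki = decay * env[idx] + (1 - decay) * npki
    if not accepted:
        raise NoBeatsError("no peaks above adaptive threshold")

    # refine to raw-signal argmax around the trigger (removes envelope lag)
    half = max(1, int(round(cfg.refine_window * fs)))
    refined = []
    for idx in accepted:
        lo, hi = max(0, idx - half), min(ecg.values.size, idx + half + 1)
        refined.append(lo + int(np.argmax(ecg.values[lo:hi])))
    peaks = np.unique(refined)

    # enforce refractory after refinement (keep larger raw amplitude)
    keep: list[int] = []
    for p in peaks:
        if keep and (p - keep[-1]) < refractory_n:
            if ecg.values[p] > ecg.values[keep[-1]]:
                keep[-1] = p
        else:
            keep.append(p)
    return ecg.start_time + np.asarray(keep, dtype=float) / fs


def ecg_to_rri(ecg: SampledSignal, cfg: QrsConfig | None = None) -> RriSeries:
    """Detect R-peaks and build the RR-interval series (ms)."""
    peaks = detect_r_peaks(ecg, cfg)
    if peaks.size < 2:
        raise InsufficientDataError("fewer than 2 detected beats")
    intervals = np.diff(peaks) * 1000.0
    return RriSeries(intervals, peaks[1:])
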
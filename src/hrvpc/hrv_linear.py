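"""Time-domain and frequency-domain (Welch) HRV metrics for a 5-min segment.

Time-domain definitions follow the consensual standards: sample SD (n-1)
throughout, mean/sd heart rate from the per-beat instantaneous HR
(HR_i = 60000 / RR_i), RMSSD the root-mean-square of successive differences,
NN50 the count of successive differences strictly greater than 50 ms.

Spectral analysis runs on the cubic-spline 4 Hz resampled series after
3rd-order polynomial detrending, using Welch's periodogram (Hann window,
window length min(duration, 256 s), 50% overlap). Bands: VLF 0.003-0.04,
LF 0.04-0.15, HF 0.15-0.4 Hz; normalized units divide by (total - VLF).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError, ValidationError
from .preprocess import detrend_poly, resample_spline
from .signal_io import RriSeries, SampledSignal

__all__ = [
    "TimeDomainMetrics",
    "SpectralBands",
    "FreqDomainMetrics",
    "time_domain_metrics",
    "welch_psd",
    "band_metrics",
    "frequency_domain_metrics",
]


@dataclass
class TimeDomainMetrics:
    mean_RR: float  # ms
    sd_RR: float    # ms
    mean_HR: float  # bpm
    sd_HR: float    # bpm
    RMSSD: float    # ms
    NN50: int
    pNN50: float    # %

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_RR": self.mean_RR, "sd_RR": self.sd_RR,
            "mean_HR": self.mean_HR, "sd_HR": self.sd_HR,
            "RMSSD": self.RMSSD, "NN50": float(self.NN50), "pNN50": self.pNN50,
        }


@dataclass
class SpectralBands:
    vlf: tuple[float, float] = (0.003, 0.04)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.40)

    def __post_init__(self) -> None:
        lo = [self.vlf[0], self.lf[0], self.hf[0]]
        hi = [self.vlf[1], self.lf[1], self.hf[1]]
        if not all(a < b for a, b in zip(lo, hi)) or not all(
                hi[i] <= lo[i + 1] for i in range(2)):
            raise ValidationError("bands must be ordered and non-overlapping")


@dataclass
class FreqDomainMetrics:
    LF_peak: float       # Hz
    HF_peak: float       # Hz
    LF_power: float      # ms^2
    HF_power: float      # ms^2
    tot_power: float     # ms^2
    LF_power_prc: float  # %
    HF_power_prc: float  # %
    LF_power_nu: float   # n.u.
    HF_power_nu: float   # n.u.
    LF_HF_power: float   # ratio

    def as_dict(self) -> dict[str, float]:
        return {
            "LF_peak": self.LF_peak, "HF_peak": self.HF_peak,
            "LF_power": self.LF_power, "LF_power_prc": self.LF_power_prc,
            "LF_power_nu": self.LF_power_nu, "HF_power": self.HF_power,
            "HF_power_prc": self.HF_power_prc, "HF_power_nu": self.HF_power_nu,
            "LF_HF_power": self.LF_HF_power, "tot_power": self.tot_power,
        }


def time_domain_metrics(rri: RriSeries) -> TimeDomainMetrics:
    iv = rri.intervals
    n = iv.size
    if n < 2:
        raise InsufficientDataError("need at least 2 beats")
    hr = 60000.0 / iv
    diff = np.diff(iv)
    nn50 = int(np.sum(np.abs(diff) > 50.0))
    return TimeDomainMetrics(
        mean_RR=float(iv.mean()),
        sd_RR=float(iv.std(ddof=1)),
        mean_HR=float(hr.mean()),
        sd_HR=float(hr.std(ddof=1)),
        RMSSD=float(np.sqrt(np.mean(diff ** 2))),
        NN50=nn50,
        pNN50=100.0 * nn50 / (n - 1),
    )


def welch_psd(x: SampledSignal, window_s: float = 256.0, overlap: float = 0.5,
              variance_normalize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD (freq Hz, density ms^2/Hz), Hann window.

    With ``variance_normalize`` the density is rescaled so its integral over
    (0, fs/2] equals the variance of the (mean-removed) input exactly, so
    band powers are expressed in genuine ms^2 of signal variance (Parseval)
    regardless of windowing losses at finite length.
    """
    n = x.values.size
    if (n - 1) / x.fs < 60:
        raise InsufficientDataError("need at least 60 s of signal for Welch PSD")
    nperseg = int(min(n, round(window_s * x.fs)))
    freqs, psd = sps.welch(
        x.values, fs=x.fs, window="hann", nperseg=nperseg,
        noverlap=int(overlap * nperseg), detrend="constant", scaling="density")
    if variance_normalize:
        integral = np.trapezoid(psd, freqs)
        var = float(np.var(x.values))
        if integral > 0 and var > 0:
            psd = psd * (var / integral)
    return freqs, psd


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def _band_peak(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float],
               mode: str = "argmax") -> float:
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        return math.nan
    if mode == "centroid":
        power = np.trapezoid(psd[mask], freqs[mask])
        if power <= 0:
            return math.nan
        return float(np.trapezoid(freqs[mask] * psd[mask], freqs[mask]) / power)
    return float(freqs[mask][np.argmax(psd[mask])])


def band_metrics(spectrum: tuple[np.ndarray, np.ndarray],
                 bands: SpectralBands | None = None,
                 peak_mode: str = "argmax") -> FreqDomainMetrics:
    """Band powers (trapezoidal), percentages, normalized units, peaks.

    ``peak_mode`` selects the band-peak convention: "argmax" (frequency of
    the highest density, default) or "centroid" (power-weighted mean
    frequency).
    """
    bands = bands or SpectralBands()
    freqs, psd = spectrum
    if freqs[-1] < bands.hf[1]:
        raise ValidationError("spectrum does not cover the HF band")
    vlf = _band_power(freqs, psd, bands.vlf)
    lf = _band_power(freqs, psd, bands.lf)
    hf = _band_power(freqs, psd, bands.hf)
    tot = vlf + lf + hf
    denom_nu = tot - vlf
    if hf == 0:
        warnings.warn("HF power is zero; LF/HF ratio reported as +inf")
        ratio = math.inf
    else:
        ratio = lf / hf
    return FreqDomainMetrics(
        LF_peak=_band_peak(freqs, psd, bands.lf, peak_mode),
        HF_peak=_band_peak(freqs, psd, bands.hf, peak_mode),
        LF_power=lf, HF_power=hf, tot_power=tot,
        LF_power_prc=100.0 * lf / tot if tot > 0 else math.nan,
        HF_power_prc=100.0 * hf / tot if tot > 0 else math.nan,
        LF_power_nu=100.0 * lf / denom_nu if denom_nu > 0 else math.nan,
        HF_power_nu=100.0 * hf / denom_nu if denom_nu > 0 else math.nan,
        LF_HF_power=ratio,
    )


def frequency_domain_metrics(rri: RriSeries, fs_resample: float = 4.0,
                             detrend_order: int = 3,
                             bands: SpectralBands | None = None) -> FreqDomainMetrics:
    """Full spectral chain: spline resample -> poly detrend -> Welch -> bands."""
    resampled = resample_spline(rri, fs_out=fs_resample)
    detrended = detrend_poly(resampled, order=detrend_order)
    return band_metrics(welch_psd(detrended), bands)
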
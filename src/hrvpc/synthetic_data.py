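"""Synthetic RR-interval, subject, cohort and ECG generators.

The beat generator is an integral pulse frequency modulation (IPFM) model:
a modulation signal

    m(t) = 1 + a_LF sin(2 pi f_LF t + phi1) + a_HF sin(2 pi f_HF t + phi2)
             + noise_sd * z_beta(t)

drives the integrator  int m(t)/Tbar dt  and a beat is emitted each time the
running integral crosses an integer (Tbar = 60/target_HR s). a_LF and a_HF
place sympathovagal-like oscillations directly in the LF and HF spectral
bands; z_beta is unit-variance 1/f^beta noise whose spectral exponent moves
the fractal metrics (higher beta -> smoother, lower-dimensional dynamics).

The default two-group, two-position cohort preset emulates a stand-up
challenge in diffuse vs limited cutaneous systemic sclerosis: the diffuse
group has a higher heart rate in both positions, a larger orthostatic HR
rise, and *loses* variability and complexity on standing (negative sd_HR,
SD2 and CorDim deltas) while the limited group gains them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .signal_io import CohortManifest, RriSeries, SampledSignal, write_rri

__all__ = [
    "GeneratorParams",
    "CohortPreset",
    "ipfm_generate",
    "make_cohort",
    "generate_cohort_series",
    "synth_ecg",
    "inject_ectopic",
    "colored_noise",
    "default_preset",
]


@dataclass
class GeneratorParams:
    """Knobs of the IPFM generator for one subject-position cell."""

    target_HR: float = 70.0   # bpm
    a_LF: float = 0.03        # fractional LF modulation amplitude
    a_HF: float = 0.03        # fractional HF modulation amplitude
    f_LF: float = 0.1         # Hz
    f_HF: float = 0.25        # Hz
    noise_sd: float = 0.02    # fractional SD of the 1/f^beta noise term
    noise_beta: float = 1.0   # spectral exponent of the noise
    duration: float = 300.0   # s
    seed: int = 0

    def validate(self) -> None:
        if not (30 <= self.target_HR <= 200):
            raise ValidationError("target_HR must lie in [30, 200] bpm")
        if self.a_LF < 0 or self.a_HF < 0 or self.noise_sd < 0:
            raise ValidationError("modulation amplitudes must be >= 0")
        if self.a_LF + self.a_HF + 3 * self.noise_sd >= 1:
            raise ValidationError(
                "a_LF + a_HF + 3*noise_sd must be < 1 to keep intervals positive")
        if not (0 <= self.noise_beta <= 2):
            raise ValidationError("noise_beta must lie in [0, 2]")
        if self.duration <= 0:
            raise ValidationError("duration must be positive")


def colored_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian 1/f^beta noise via spectral shaping."""
    white = rng.standard_normal(n)
    if beta == 0 or n < 4:
        white -= white.mean()
        sd = white.std()
        return white / sd if sd > 0 else white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid the DC singularity
    spec *= f ** (-beta / 2.0)
    x = np.fft.irfft(spec, n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def ipfm_generate(params: GeneratorParams) -> RriSeries:
    """Emit beats where the integral of m(t)/Tbar crosses successive integers."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs_mod = 8.0  # internal modulation sampling, Hz
    n = int(params.duration * fs_mod) + 1
    t = np.arange(n) / fs_mod
    phi1, phi2 = rng.uniform(0, 2 * math.pi, size=2)
    m = (1.0
         + params.a_LF * np.sin(2 * math.pi * params.f_LF * t + phi1)
         + params.a_HF * np.sin(2 * math.pi * params.f_HF * t + phi2))
    if params.noise_sd > 0:
        m = m + params.noise_sd * colored_noise(n, params.noise_beta, rng)
    if (m <= 0).any():
        raise ValidationError(
            "modulation signal dips below zero; lower amplitudes/noise_sd")
    tbar = 60.0 / params.target_HR
    integral = np.concatenate(([0.0], np.cumsum((m[1:] + m[:-1]) / 2.0) / fs_mod)) / tbar
    n_beats = int(math.floor(integral[-1]))
    if n_beats < 2:
        raise ValidationError("duration too short to emit beats")
    # invert the monotone integral at integer thresholds
    beat_times = np.interp(np.arange(1, n_beats + 1), integral, t)
    intervals = np.diff(beat_times) * 1000.0
    return RriSeries(intervals, beat_times[1:])


@dataclass
class CohortPreset:
    """Generator parameters per group x position cell, plus group sizes.

    The defaults are chosen to reproduce the direction and ordering of the
    group-by-position structure of a diffuse vs limited systemic-sclerosis
    stand-up study: see `default_preset`.
    """

    cells: dict[tuple[str, str], GeneratorParams]
    n_dcssc: int = 16
    n_lcssc: int = 42
    hr_jitter_sd: float = 0.09      # log-normal sigma on subject HR
    knob_jitter_sd: float = 0.18    # log-normal sigma on amplitude/noise knobs

    def __post_init__(self) -> None:
        need = {(g, p) for g in ("dcSSc", "lcSSc") for p in ("S1", "S2")}
        if set(self.cells) != need:
            raise ValidationError("preset requires the four group x position cells")
        if self.n_dcssc <= 0 or self.n_lcssc <= 0:
            raise ValidationError("group sizes must be positive")


def default_preset() -> CohortPreset:
    """Two-group stand-up preset.

    Heart rates follow the group-by-position means (74/88 bpm diffuse,
    68/77 bpm limited). On standing, the diffuse cells lose modulation
    amplitude and broadband noise while the noise spectrum steepens
    (smoother, lower-dimensional dynamics); the limited cells do the
    opposite. This yields dcSSc > lcSSc mean HR in both positions and
    opposite-signed group means of sd_HR, SD2 and CorDim deltas.
    """
    return CohortPreset(cells={
        ("dcSSc", "S1"): GeneratorParams(target_HR=74, a_LF=0.035, a_HF=0.032,
                                         noise_sd=0.028, noise_beta=0.9),
        ("dcSSc", "S2"): GeneratorParams(target_HR=88, a_LF=0.030, a_HF=0.008,
                                         noise_sd=0.008, noise_beta=1.8),
        ("lcSSc", "S1"): GeneratorParams(target_HR=68, a_LF=0.035, a_HF=0.030,
                                         noise_sd=0.018, noise_beta=1.2),
        ("lcSSc", "S2"): GeneratorParams(target_HR=77, a_LF=0.050, a_HF=0.022,
                                         noise_sd=0.038, noise_beta=0.6),
    })


def _jitter_params(base: GeneratorParams, hr_factor: float, knob_factor: float,
                   seed: int) -> GeneratorParams:
    p = replace(
        base,
        target_HR=float(np.clip(base.target_HR * hr_factor, 35, 180)),
        a_LF=base.a_LF * knob_factor,
        a_HF=base.a_HF * knob_factor,
        noise_sd=base.noise_sd * knob_factor,
        seed=seed,
    )
    # keep the positivity invariant under jitter
    total = p.a_LF + p.a_HF + 3 * p.noise_sd
    if total >= 0.95:
        shrink = 0.95 / total
        p = replace(p, a_LF=p.a_LF * shrink, a_HF=p.a_HF * shrink,
                    noise_sd=p.noise_sd * shrink)
    return p


def generate_cohort_series(preset: CohortPreset | None = None, seed: int = 0
                           ) -> tuple[pd.DataFrame, dict[tuple[str, str], RriSeries]]:
    """Generate per-subject S1/S2 RR series in memory.

    Returns (ground-truth parameter table, {(subject_id, position): series}).
    Subject-level jitter (heart rate and variability knobs) is shared
    between the two positions so stand-up deltas stay coherent within a
    subject.
    """
    preset = preset or default_preset()
    rng = np.random.default_rng(seed)
    truth_rows = []
    series: dict[tuple[str, str], RriSeries] = {}
    subjects = [("dcSSc", i) for i in range(preset.n_dcssc)] + \
               [("lcSSc", i) for i in range(preset.n_lcssc)]
    for group, i in subjects:
        sid = f"{group.lower()}_{i:03d}"
        hr_factor = float(np.exp(rng.normal(0, preset.hr_jitter_sd)))
        knob_factor = float(np.exp(rng.normal(0, preset.knob_jitter_sd)))
        # subject-specific oscillation frequencies (baroreflex resonance and
        # respiratory rate differ across people)
        f_lf = float(rng.uniform(0.08, 0.12))
        f_hf = float(rng.uniform(0.20, 0.32))
        for pos in ("S1", "S2"):
            cell = preset.cells[(group, pos)]
            # mild per-position jitter on top of the shared subject factor
            pos_hr = hr_factor * float(np.exp(rng.normal(0, 0.02)))
            pos_knob = knob_factor * float(np.exp(rng.normal(0, 0.05)))
            p = _jitter_params(cell, pos_hr, pos_knob,
                               seed=int(rng.integers(2 ** 31)))
            p = replace(p, f_LF=f_lf, f_HF=f_hf)
            series[(sid, pos)] = ipfm_generate(p)
            truth_rows.append({"subject_id": sid, "group": group, "position": pos,
                               "target_HR": p.target_HR, "a_LF": p.a_LF,
                               "a_HF": p.a_HF, "f_LF": p.f_LF, "f_HF": p.f_HF,
                               "noise_sd": p.noise_sd,
                               "noise_beta": p.noise_beta, "seed": p.seed})
    return pd.DataFrame(truth_rows), series


def make_cohort(preset: CohortPreset | None = None, seed: int = 0,
                out_dir: str | Path = ".") -> tuple[CohortManifest, pd.DataFrame]:
    """Write per-subject RRI files plus a manifest; return manifest and truth."""
    preset = preset or default_preset()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth, series = generate_cohort_series(preset, seed)
    rows = []
    for sid in truth["subject_id"].unique():
        group = truth.loc[truth.subject_id == sid, "group"].iloc[0]
        paths = {}
        for pos in ("S1", "S2"):
            path = out_dir / f"{sid}_{pos}.rri"
            write_rri(series[(sid, pos)], path, dialect="plain_ms")
            paths[pos] = str(path)
        rows.append({"subject_id": sid, "group": group,
                     "path_S1": paths["S1"], "path_S2": paths["S2"],
                     "input_kind": "rri"})
    manifest = CohortManifest(pd.DataFrame(rows))
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    manifest.rows.to_csv(out_dir / "manifest.csv", index=False)
    return manifest, truth


def _qrs_template(fs: float, width_s: float = 0.080) -> np.ndarray:
    """Biphasic wavelet (Mexican-hat-like) QRS template of ~80 ms."""
    half = int(width_s * fs / 2)
    t = np.arange(-half, half + 1) / fs
    s = width_s / 6.0
    u = t / s
    return (1 - u ** 2) * np.exp(-(u ** 2) / 2)


def synth_ecg(rri: RriSeries, fs: float = 1000.0, snr_db: float | None = None,
              seed: int = 0) -> tuple[SampledSignal, np.ndarray]:
    """Render a synthetic single-lead ECG from beat times.

    Places a QRS template at each beat time, adds a 0.3 Hz baseline-wander
    sine and (optionally) white Gaussian noise at the requested SNR.
    Returns the signal and the ground-truth beat times.
    """
    if fs < 100:
        raise ValidationError(f"sampling rate {fs} Hz unsupported (need >= 100 Hz)")
    if rri.n_beats == 0:
        raise ValidationError("empty RR series")
    beat_times = rri.beat_times
    t_end = beat_times[-1] + 0.5
    n = int(t_end * fs) + 1
    sig = np.zeros(n)
    tmpl = _qrs_template(fs)
    half = tmpl.size // 2
    for bt in beat_times:
        c = int(round(bt * fs))
        lo, hi = c - half, c + half + 1
        s_lo, s_hi = max(lo, 0), min(hi, n)
        sig[s_lo:s_hi] += tmpl[s_lo - lo: tmpl.size - (hi - s_hi)]
    t = np.arange(n) / fs
    sig = sig + 0.1 * np.sin(2 * math.pi * 0.3 * t)  # baseline wander
    if snr_db is not None:
        rng = np.random.default_rng(seed)
        p_sig = float(np.mean(sig ** 2))
        p_noise = p_sig / (10 ** (snr_db / 10))
        sig = sig + rng.normal(0, math.sqrt(p_noise), n)
    return SampledSignal(sig, fs=fs), beat_times.copy()


def inject_ectopic(rri: RriSeries, rate_per_100: float, seed: int = 0
                   ) -> tuple[RriSeries, np.ndarray]:
    """Split selected beats into a premature beat (40% of the interval) plus
    the compensatory remainder; returns the new series and the indices (in
    the new series) of the premature beats."""
    if rate_per_100 < 0:
        raise ValidationError("ectopic rate must be >= 0")
    n = rri.n_beats
    n_inject = int(round(rate_per_100 * n / 100.0))
    if n_inject == 0:
        return rri, np.array([], dtype=int)
    if n_inject * 3 > n:
        raise ValidationError("ectopic rate too high: injection windows overlap")
    rng = np.random.default_rng(seed)
    # keep injections separated so compensatory pairs never touch
    candidates = np.arange(1, n - 1)
    chosen: list[int] = []
    rng.shuffle(candidates)
    for idx in candidates:
        if all(abs(idx - c) > 2 for c in chosen):
            chosen.append(int(idx))
        if len(chosen) == n_inject:
            break
    chosen.sort()
    new_iv: list[float] = []
    positions = []
    for i, v in enumerate(rri.intervals):
        if i in chosen:
            positions.append(len(new_iv))
            new_iv.append(0.4 * v)
            new_iv.append(0.6 * v)
        else:
            new_iv.append(float(v))
    t0 = rri.beat_times[0] - rri.intervals[0] / 1000.0
    return RriSeries.from_intervals(new_iv, t0=t0), np.asarray(positions, dtype=int)
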
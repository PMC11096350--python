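"""Nonlinear-domain HRV metrics.

Implements, on the corrected beat-to-beat RR series:

* Poincare plot geometry (SD1, SD2, SD1/SD2) via the variance identities
  SD1^2 = mean(dRR^2)/2 (so SD1 = RMSSD/sqrt(2) exactly) and
  SD2^2 = 2 var(RR) - mean(dRR^2)/2 (population variance, clipped at 0);
* recurrence quantification (REC, DET, Lmin/Lmean/Lmax, DIV, ShanEn) on a
  time-delay embedding with m=10, tau=1 and radius sqrt(m)*SD (Euclidean
  norm, line of identity excluded, minimum counted line length 2);
* detrended fluctuation analysis alpha1 (box sizes 4..16) and alpha2
  (16..64), non-overlapping boxes, order-1 per-box detrending;
* approximate and sample entropy (m=2, r=0.2*SD, Chebyshev distance; ApEn
  includes self-matches, SampEn excludes them);
* the Grassberger-Procaccia correlation sum and correlation dimension
  (m=10, tau=1). CorDim estimates the r->0 limit of log C / log r as the
  local least-squares slope over the 5 consecutive usable points of a
  30-point geometric radius grid spanning [0.025, 1.0]*SD, positioned
  nearest r = 0.15*SD (usable = radii where 0 < C < 1, so for sparse sums
  the window slides to the smallest radii where pairs exist). Embedded
  distances in cordim are per-coordinate RMS (Euclidean/sqrt(m)) so the
  radius grid is commensurate with the series SD at any m.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import InsufficientDataError, ValidationError
from .signal_io import RriSeries

__all__ = [
    "EmbeddingConfig",
    "PoincareMetrics",
    "RqaMetrics",
    "FractalEntropyMetrics",
    "poincare",
    "rqa",
    "dfa",
    "apen",
    "sampen",
    "correlation_sum",
    "cordim",
    "embed",
]


@dataclass
class EmbeddingConfig:
    """Time-delay embedding parameters (lag counted in beats)."""

    m: int = 10
    tau: int = 1
    norm: Literal["euclidean", "chebyshev"] = "euclidean"

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ValidationError("embedding dimension and lag must be >= 1")


@dataclass
class PoincareMetrics:
    SD1: float
    SD2: float
    SD1_SD2: float


@dataclass
class RqaMetrics:
    Lmin: float
    Lmean: float
    Lmax: float
    DIV: float
    REC: float   # %
    DET: float   # %
    ShanEn: float  # nats

    def as_dict(self) -> dict[str, float]:
        return {"Lmin": self.Lmin, "Lmean": self.Lmean, "Lmax": self.Lmax,
                "DIV": self.DIV, "REC": self.REC, "DET": self.DET,
                "ShanEn": self.ShanEn}


@dataclass
class FractalEntropyMetrics:
    alpha1: float
    alpha2: float
    ApEn: float
    SampEn: float
    CorDim: float


def embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Time-delay embedding matrix of shape (N-(m-1)*tau, m)."""
    x = np.asarray(x, dtype=float)
    n_vec = x.size - (m - 1) * tau
    if n_vec < 2:
        raise InsufficientDataError(
            f"series of {x.size} too short for m={m}, tau={tau} embedding")
    idx = np.arange(n_vec)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def poincare(rri: RriSeries) -> PoincareMetrics:
    """Lag-1 Poincare plot ellipse axes."""
    iv = rri.intervals
    if iv.size < 3:
        raise InsufficientDataError("need at least 3 beats")
    diff = np.diff(iv)
    msd = float(np.mean(diff ** 2))
    sd1 = math.sqrt(msd / 2.0)
    sd2_sq = 2.0 * float(iv.var()) - msd / 2.0
    sd2 = math.sqrt(max(sd2_sq, 0.0))
    ratio = sd1 / sd2 if sd2 > 0 else math.nan
    return PoincareMetrics(SD1=sd1, SD2=sd2, SD1_SD2=ratio)


def _pairwise(X: np.ndarray, norm: str) -> np.ndarray:
    metric = "euclidean" if norm == "euclidean" else "chebyshev"
    return squareform(pdist(X, metric=metric))


def _diagonal_lines(R: np.ndarray, lmin: int) -> list[int]:
    """Lengths (>= lmin) of diagonal 1-runs in the upper triangle of R."""
    n = R.shape[0]
    lengths: list[int] = []
    for k in range(1, n):
        diag = np.diagonal(R, offset=k)
        if not diag.any():
            continue
        padded = np.concatenate(([0], diag.view(np.uint8), [0]))
        edges = np.diff(padded)
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        runs = ends - starts
        lengths.extend(int(r) for r in runs if r >= lmin)
    return lengths


def rqa(rri: RriSeries, cfg: EmbeddingConfig | None = None,
        r: float | None = None, lmin: int = 2) -> RqaMetrics:
    """Recurrence-plot quantification of the embedded RR series.

    Default radius is sqrt(m) * SD of the series (population SD). The line
    of identity is excluded from both the recurrence rate denominator and
    the diagonal-line statistics.
    """
    cfg = cfg or EmbeddingConfig()
    iv = rri.intervals
    need = (cfg.m - 1) * cfg.tau + lmin
    if iv.size <= need:
        raise InsufficientDataError(f"need more than {need} beats for RQA")
    sd = float(iv.std())
    if r is None:
        r = math.sqrt(cfg.m) * sd
    if r <= 0:
        raise ValidationError("RQA radius must be positive")
    X = embed(iv, cfg.m, cfg.tau)
    n = X.shape[0]
    D = _pairwise(X, cfg.norm)
    R = D <= r
    np.fill_diagonal(R, False)
    n_rec = int(R.sum())  # both triangles, diagonal excluded
    rec = 100.0 * n_rec / (n * n - n)
    if n_rec == 0:
        warnings.warn("no recurrent points; RQA metrics undefined")
        nan = math.nan
        return RqaMetrics(nan, nan, nan, nan, 0.0, nan, nan)
    lengths = _diagonal_lines(R, lmin)
    if not lengths:
        warnings.warn("no diagonal lines of the minimum length")
        nan = math.nan
        return RqaMetrics(nan, nan, nan, nan, rec, 0.0, nan)
    lengths_arr = np.asarray(lengths, dtype=float)
    lmax = float(lengths_arr.max())
    # lines live in the upper triangle; recurrent points count both triangles
    det = 100.0 * 2.0 * float(lengths_arr.sum()) / n_rec
    counts = np.bincount(np.asarray(lengths, dtype=int))[lmin:]
    p = counts[counts > 0] / counts.sum()
    shanen = float(-(p * np.log(p)).sum())
    return RqaMetrics(
        Lmin=float(lengths_arr.min()),
        Lmean=float(lengths_arr.mean()),
        Lmax=lmax,
        DIV=1.0 / lmax,
        REC=rec,
        DET=min(det, 100.0),
        ShanEn=shanen,
    )


def dfa(rri: RriSeries, short: tuple[int, int] = (4, 16),
        long: tuple[int, int] = (16, 64)) -> tuple[float, float]:
    """Detrended fluctuation exponents (alpha1, alpha2)."""
    x = rri.intervals
    if x.size < 2 * long[1]:
        raise InsufficientDataError(f"need at least {2 * long[1]} beats for DFA")
    if x.std() == 0:
        raise ValidationError("constant series: DFA exponent undefined")
    y = np.cumsum(x - x.mean())

    def fluctuation(n: int) -> float:
        k = y.size // n
        segs = y[: k * n].reshape(k, n)
        t = np.arange(n, dtype=float)
        # per-box order-1 fit, vectorized over boxes
        tm = t - t.mean()
        slope = segs @ tm / (tm @ tm)
        resid = segs - segs.mean(axis=1, keepdims=True) - slope[:, None] * tm
        return math.sqrt(float(np.mean(resid ** 2)))

    def alpha(rng: tuple[int, int]) -> float:
        ns = np.arange(rng[0], rng[1] + 1)
        fs = np.array([fluctuation(int(n)) for n in ns])
        ok = fs > 0
        if ok.sum() < 2:
            raise ValidationError("fluctuation function vanishes; exponent undefined")
        return float(np.polyfit(np.log(ns[ok]), np.log(fs[ok]), 1)[0])

    return alpha(short), alpha(long)


def _phi_counts(x: np.ndarray, m: int, r: float, exclude_self: bool) -> np.ndarray:
    """Per-template counts of Chebyshev matches at template length m.

    Uses N - m_max templates is NOT assumed here; the caller controls the
    template count via slicing.
    """
    templates = embed(x, m, 1)
    D = _pairwise(templates, "chebyshev")
    match = D <= r
    if exclude_self:
        np.fill_diagonal(match, False)
    return match.sum(axis=1)


def apen(rri: RriSeries, m: int = 2, r: float | None = None) -> float:
    """Approximate entropy (self-matches included), natural log."""
    x = rri.intervals
    if x.size < m + 2:
        raise InsufficientDataError("series too short for ApEn")
    sd = float(x.std())
    if sd == 0:
        raise ValidationError("constant series: r = 0.2*SD is zero")
    if r is None:
        r = 0.2 * sd

    def phi(mm: int) -> float:
        counts = _phi_counts(x, mm, r, exclude_self=False)
        c = counts / counts.size
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def sampen(rri: RriSeries, m: int = 2, r: float | None = None) -> float:
    """Sample entropy -ln(A/B), self-matches excluded, Chebyshev distance.

    Both template lengths use the same N-m templates so every length-m
    template has a length-(m+1) extension.
    """
    x = rri.intervals
    if x.size < m + 2:
        raise InsufficientDataError("series too short for SampEn")
    sd = float(x.std())
    if sd == 0:
        raise ValidationError("constant series: r = 0.2*SD is zero")
    if r is None:
        r = 0.2 * sd
    tmpl_m1 = embed(x, m + 1, 1)          # N - m templates of length m+1
    tmpl_m = tmpl_m1[:, :m]               # their length-m prefixes
    Dm = _pairwise(tmpl_m, "chebyshev")
    Dm1 = _pairwise(tmpl_m1, "chebyshev")
    iu = np.triu_indices(tmpl_m.shape[0], k=1)
    B = int((Dm[iu] <= r).sum())
    A = int((Dm1[iu] <= r).sum())
    if A == 0 or B == 0:
        warnings.warn("no template matches; SampEn undefined")
        return math.nan
    return -math.log(A / B)


def correlation_sum(rri: RriSeries, m: int, tau: int, r: float,
                    norm: str = "euclidean") -> float:
    """Fraction of embedded point pairs closer than r (Heaviside >= 0).

    C = 2/(M(M-1)) * sum_{i<j} H(r - ||X_i - X_j||). The textbook prefactor
    1/(N(N-1)) over an i<j sum yields exactly half this value; the constant
    cancels in log-log slopes, and the fraction-of-pairs convention keeps
    C(r) -> 1 for large r.
    """
    if r <= 0:
        raise ValidationError("radius r must be positive")
    X = embed(rri.intervals, m, tau)
    d = pdist(X, metric="euclidean" if norm == "euclidean" else "chebyshev")
    return float(np.mean(d <= r))


def cordim(rri: RriSeries, cfg: EmbeddingConfig | None = None,
           r_center_frac: float = 0.15, n_grid: int = 30,
           window: int = 5) -> float:
    """Grassberger-Procaccia correlation dimension.

    Local log-log slope of the correlation sum over ``window`` radius-grid
    points centered nearest ``r_center_frac * SD`` of the series; radii span
    [0.025, 1.0]*SD geometrically. Distances are per-coordinate RMS so the
    grid scale is independent of the embedding dimension. Result clipped to
    [0, m]; NaN when fewer than 3 window points have 0 < C < 1.
    """
    cfg = cfg or EmbeddingConfig()
    iv = rri.intervals
    if iv.size < 100:
        raise InsufficientDataError("need at least 100 beats for CorDim")
    sd = float(iv.std())
    if sd == 0:
        return 0.0
    X = embed(iv, cfg.m, cfg.tau)
    d = pdist(X, metric="euclidean") / math.sqrt(cfg.m)
    radii = sd * np.geomspace(0.025, 1.0, n_grid)
    C = np.array([np.mean(d <= r) for r in radii])
    # the limit is estimable only where 0 < C < 1; slide a window of
    # consecutive usable grid points to the position nearest r_center on the
    # log-radius axis (for sparse sums this lands on the smallest radii
    # where pairs exist)
    usable = np.flatnonzero((C > 0) & (C < 1))
    if usable.size < 3:
        warnings.warn("too few usable correlation-sum points; CorDim undefined")
        return math.nan
    w = min(window, usable.size)
    target = math.log(r_center_frac * sd)
    best_idx = min(
        (usable[s:s + w] for s in range(usable.size - w + 1)),
        key=lambda idx: abs(float(np.mean(np.log(radii[idx]))) - target))
    slope = float(np.polyfit(np.log(radii[best_idx]), np.log(C[best_idx]), 1)[0])
    return float(np.clip(slope, 0.0, cfg.m))
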
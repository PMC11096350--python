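"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain double loops straight from the metric
definitions, deliberately ignoring the vectorized implementations under
test.
"""

from __future__ import annotations

import math

import numpy as np


def time_domain_reference(iv: np.ndarray) -> dict[str, float]:
    """Single-pass literal evaluation of the time-domain definitions."""
    iv = np.asarray(iv, dtype=float)
    n = len(iv)
    mean_rr = sum(iv) / n
    sd_rr = math.sqrt(sum((x - mean_rr) ** 2 for x in iv) / (n - 1))
    hr = [60000.0 / x for x in iv]
    mean_hr = sum(hr) / n
    sd_hr = math.sqrt(sum((h - mean_hr) ** 2 for h in hr) / (n - 1))
    diffs = [iv[i + 1] - iv[i] for i in range(n - 1)]
    rmssd = math.sqrt(sum(d * d for d in diffs) / len(diffs))
    nn50 = sum(1 for d in diffs if abs(d) > 50.0)
    return {"mean_RR": mean_rr, "sd_RR": sd_rr, "mean_HR": mean_hr,
            "sd_HR": sd_hr, "RMSSD": rmssd, "NN50": float(nn50),
            "pNN50": 100.0 * nn50 / (n - 1)}


def embed_reference(x: np.ndarray, m: int, tau: int) -> list[tuple[float, ...]]:
    x = list(map(float, x))
    return [tuple(x[i + j * tau] for j in range(m))
            for i in range(len(x) - (m - 1) * tau)]


def _cheb(a, b) -> float:
    return max(abs(u - v) for u, v in zip(a, b))


def _eucl(a, b) -> float:
    return math.sqrt(sum((u - v) ** 2 for u, v in zip(a, b)))


def apen_reference(x: np.ndarray, m: int, r: float) -> float:
    """Literal template counting with self-matches included."""
    def phi(mm: int) -> float:
        tmpl = embed_reference(x, mm, 1)
        n = len(tmpl)
        total = 0.0
        for a in tmpl:
            c = sum(1 for b in tmpl if _cheb(a, b) <= r)
            total += math.log(c / n)
        return total / n
    return phi(m) - phi(m + 1)


def sampen_reference(x: np.ndarray, m: int, r: float) -> float:
    """Literal pair counting, self-matches excluded, same template count
    at lengths m and m+1."""
    tmpl1 = embed_reference(x, m + 1, 1)
    tmpl0 = [t[:m] for t in tmpl1]
    n = len(tmpl1)
    B = sum(1 for i in range(n) for j in range(i + 1, n)
            if _cheb(tmpl0[i], tmpl0[j]) <= r)
    A = sum(1 for i in range(n) for j in range(i + 1, n)
            if _cheb(tmpl1[i], tmpl1[j]) <= r)
    if A == 0 or B == 0:
        return math.nan
    return -math.log(A / B)


def correlation_sum_reference(x: np.ndarray, m: int, tau: int, r: float) -> float:
    """Fraction of embedded pairs with Euclidean distance <= r."""
    pts = embed_reference(x, m, tau)
    n = len(pts)
    hits = sum(1 for i in range(n) for j in range(i + 1, n)
               if _eucl(pts[i], pts[j]) <= r)
    return 2.0 * hits / (n * (n - 1))


def rqa_reference(x: np.ndarray, m: int, tau: int, r: float,
                  lmin: int = 2) -> dict[str, float]:
    """Materialize the full recurrence matrix and enumerate diagonal lines."""
    pts = embed_reference(x, m, tau)
    n = len(pts)
    R = [[1 if i != j and _eucl(pts[i], pts[j]) <= r else 0
          for j in range(n)] for i in range(n)]
    n_rec = sum(R[i][j] for i in range(n) for j in range(n))
    rec = 100.0 * n_rec / (n * n - n)
    lengths = []
    for k in range(1, n):  # upper-triangle diagonals
        run = 0
        for i in range(n - k):
            if R[i][i + k]:
                run += 1
            else:
                if run >= lmin:
                    lengths.append(run)
                run = 0
        if run >= lmin:
            lengths.append(run)
    out = {"REC": rec}
    if n_rec == 0:
        out.update({k: math.nan for k in
                    ("Lmin", "Lmean", "Lmax", "DIV", "DET", "ShanEn")})
        out["REC"] = 0.0
        return out
    if not lengths:
        out.update({k: math.nan for k in ("Lmin", "Lmean", "Lmax", "DIV", "ShanEn")})
        out["DET"] = 0.0
        return out
    out["Lmin"] = float(min(lengths))
    out["Lmean"] = sum(lengths) / len(lengths)
    out["Lmax"] = float(max(lengths))
    out["DIV"] = 1.0 / max(lengths)
    out["DET"] = min(100.0, 100.0 * 2.0 * sum(lengths) / n_rec)
    from collections import Counter
    counts = Counter(lengths)
    total = sum(counts.values())
    out["ShanEn"] = -sum((c / total) * math.log(c / total)
                         for c in counts.values())
    return out


def confusion_reference(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    prec = tp / (tp + fp)
    acc = (tp + tn) / (tp + fn + tn + fp)
    f1 = 2 * prec * sens / (prec + sens)
    return {"Sensitivity": sens, "Specificity": spec, "Precision": prec,
            "Accuracy": acc, "F1": f1}
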
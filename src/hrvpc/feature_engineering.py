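"""Feature screening, collinearity pruning, scaling, ranking and selection.

Five selectors rank every candidate feature (bagged-tree impurity, extra-
trees impurity, univariate F-score, univariate mutual information, recursive
elimination with a linear classifier). The rankings are aggregated by a
redundancy-weighted score: mean rank plus the across-selector rank standard
deviation, so a feature is penalised both for ranking poorly on average and
for ranking inconsistently. An independent univariate separability index
(gamma = |mu1 - mu2| / sqrt(sigma1^2 + sigma2^2)) provides a second,
discriminability-driven ordering; the final top-k takes the intersection of
both top lists first and fills remaining slots by an arbiter policy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.feature_selection import RFE, f_classif, mutual_info_classif
from sklearn.linear_model import LogisticRegression

from .errors import PipelineError, ValidationError
from .cohort_stats import univariate_compare
from .protocol import CohortTable

__all__ = [
    "SelectionConfig",
    "screen_univariate",
    "prune_collinear",
    "minmax_scale",
    "rank_features",
    "gamma_rank",
    "select_top",
]

#: metrics regarded as physiologically primary when a collinear pair must be
#: broken; earlier entries are preferred for keeping
_KEEP_PRIORITY = ("mean_HR", "sd_HR", "SD2", "CorDim", "mean_RR", "SD1",
                  "RMSSD", "sd_RR", "LF_power", "HF_power", "SampEn", "ApEn",
                  "alpha1", "alpha2", "ShanEn", "DET", "REC", "Lmean", "Lmax",
                  "tot_power", "LF_HF_power")


@dataclass
class SelectionConfig:
    r2_threshold: float = 0.9
    screen_p: float = 0.1
    n_top: int = 5
    rank_sd_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.r2_threshold <= 1):
            raise ValidationError("r2_threshold must lie in (0, 1]")
        if self.n_top < 1:
            raise ValidationError("n_top must be >= 1")


def screen_univariate(cohort: CohortTable, alpha: float = 0.1,
                      features: list[str] | None = None) -> list[str]:
    """Keep features whose unadjusted univariate group-comparison p < alpha."""
    candidates = features or list(cohort.features.columns)
    kept = []
    for feat in candidates:
        try:
            res = univariate_compare(cohort, feat)
        except Exception:
            continue
        if res.p_unadjusted < alpha:
            kept.append(feat)
    if not kept:
        raise PipelineError(
            f"no features survive univariate screening at alpha={alpha}; "
            "consider relaxing the threshold")
    return kept


def _keep_score(name: str) -> tuple[int, int, str]:
    """Lower = more preferred to keep: deltas first, then priority metrics."""
    is_delta = 0 if name.endswith("_delta") else 1
    base = name.rsplit("_", 1)[0]
    try:
        prio = _KEEP_PRIORITY.index(base)
    except ValueError:
        prio = len(_KEEP_PRIORITY)
    return (is_delta, prio, name)


def prune_collinear(cohort: CohortTable, features: list[str],
                    r2_threshold: float = 0.9
                    ) -> tuple[list[str], list[dict]]:
    """Greedy removal of one member of every pair with R^2 above threshold.

    Pairs are visited in descending R^2 (ties by name) and the member with
    the worse keep-priority is dropped; the walk is deterministic and
    independent of row order.
    """
    if len(features) < 2:
        raise ValidationError("need at least 2 features to prune")
    data = cohort.frame[features].astype(float)
    corr = data.corr(method="pearson") ** 2
    pairs = []
    for i, a in enumerate(features):
        for b in features[i + 1:]:
            r2 = float(corr.loc[a, b])
            if np.isfinite(r2) and r2 > r2_threshold:
                pairs.append((r2, a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    removed: set[str] = set()
    log: list[dict] = []
    for r2, a, b in pairs:
        if a in removed or b in removed:
            continue
        keep, drop = sorted((a, b), key=_keep_score)
        removed.add(drop)
        log.append({"kept": keep, "removed": drop, "r2": r2})
    return [f for f in features if f not in removed], log


def minmax_scale(cohort: CohortTable, features: list[str]
                 ) -> tuple[pd.DataFrame, list[str]]:
    """Map each feature to [0, 1]; constant features are warned about and
    dropped before ranking."""
    data = cohort.frame[features].astype(float)
    lo, hi = data.min(), data.max()
    keep = [f for f in features if hi[f] > lo[f]]
    dropped = sorted(set(features) - set(keep))
    if dropped:
        warnings.warn(f"dropping constant features before ranking: {dropped}")
    scaled = (data[keep] - lo[keep]) / (hi[keep] - lo[keep])
    return scaled, keep


def _to_ranks(scores: np.ndarray, names: list[str]) -> pd.Series:
    """Scores (higher = better) -> ranks 1..n, deterministic tie-break by name."""
    order = sorted(range(len(names)), key=lambda i: (-scores[i], names[i]))
    ranks = np.empty(len(names), dtype=int)
    for rank, idx in enumerate(order, start=1):
        ranks[idx] = rank
    return pd.Series(ranks, index=names)


def rank_features(cohort: CohortTable, features: list[str],
                  seed: int = 0, rank_sd_weight: float = 1.0) -> pd.DataFrame:
    """Five-selector ranking aggregated by the redundancy-weighted score.

    Returns a DataFrame indexed by feature with one rank column per
    selector plus mean_rank, rank_sd, redundancy_score and final_rank
    (ascending redundancy_score; ties by mean_rank then name).
    """
    if len(features) < 2:
        raise ValidationError("need at least 2 features to rank")
    X_df, kept = minmax_scale(cohort, features)
    X = X_df.to_numpy()
    y = (cohort.labels == "dcSSc").to_numpy().astype(int)

    rf = RandomForestClassifier(n_estimators=200, random_state=seed).fit(X, y)
    et = ExtraTreesClassifier(n_estimators=200, random_state=seed).fit(X, y)
    f_scores, _ = f_classif(X, y)
    mi = mutual_info_classif(X, y, random_state=seed)
    rfe = RFE(LogisticRegression(max_iter=1000), n_features_to_select=1).fit(X, y)

    table = pd.DataFrame(index=kept)
    table["rank_1"] = _to_ranks(rf.feature_importances_, kept)
    table["rank_2"] = _to_ranks(et.feature_importances_, kept)
    table["rank_3"] = _to_ranks(np.nan_to_num(f_scores), kept)
    table["rank_4"] = _to_ranks(mi, kept)
    table["rank_5"] = pd.Series(rfe.ranking_, index=kept)  # already 1..n

    ranks = table[[f"rank_{i}" for i in range(1, 6)]]
    table["mean_rank"] = ranks.mean(axis=1)
    table["rank_sd"] = ranks.std(axis=1, ddof=1)
    table["redundancy_score"] = table["mean_rank"] + rank_sd_weight * table["rank_sd"]
    order = table.assign(_name=table.index).sort_values(
        ["redundancy_score", "mean_rank", "_name"], kind="mergesort")
    table["final_rank"] = pd.Series(
        range(1, len(order) + 1), index=order.index)
    return table.sort_values("final_rank")


def gamma_rank(cohort: CohortTable, features: list[str]) -> pd.Series:
    """Univariate separability gamma = |mu1-mu2| / sqrt(s1^2+s2^2), descending."""
    x_mask = cohort.labels == "dcSSc"
    y_mask = cohort.labels == "lcSSc"
    if x_mask.sum() < 3 or y_mask.sum() < 3:
        raise ValidationError("need two groups with >= 3 members each")
    values = {}
    for feat in features:
        a = cohort.frame.loc[x_mask, feat].astype(float)
        b = cohort.frame.loc[y_mask, feat].astype(float)
        denom = math.sqrt(a.var(ddof=1) + b.var(ddof=1))
        if denom == 0:
            warnings.warn(f"{feat}: zero pooled dispersion; gamma = inf")
            values[feat] = math.inf
        else:
            values[feat] = abs(a.mean() - b.mean()) / denom
    return pd.Series(values).sort_values(ascending=False, kind="mergesort")


def select_top(rank_table: pd.DataFrame, gamma_table: pd.Series,
               n_top: int = 5, arbiter: list[str] | None = None
               ) -> tuple[list[str], dict]:
    """Final feature set: intersection of both top-n lists first, remaining
    slots filled by the arbiter (default: redundancy-score order; an explicit
    preference list reproduces an expert override)."""
    if n_top > len(rank_table):
        raise ValidationError("n_top exceeds the number of ranked features")
    top_rank = list(rank_table.index[:n_top])
    top_gamma = list(gamma_table.index[:n_top])
    agreed = [f for f in top_rank if f in top_gamma]
    slots = n_top - len(agreed)
    pool = [f for f in (arbiter or []) if f not in agreed]
    pool += [f for f in rank_table.index if f not in agreed and f not in pool]
    filled = pool[:slots]
    info = {"agreed": agreed, "arbiter_filled": filled,
            "top_by_rank": top_rank, "top_by_gamma": top_gamma}
    return agreed + filled, info
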
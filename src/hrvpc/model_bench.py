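"""Classifier benchmark: SMOTE balancing, 1-to-5-variable combinations,
11 algorithm families, repeated stratified cross-validation, 8 metrics.

The positive class is the diffuse form (dcSSc) — the clinical target and
the minority. SMOTE is applied inside training folds by default so no
synthetic sample can leak into a validation fold; `smote_policy="before_split"`
reproduces the simpler (leakage-prone) order of balancing the whole table
first. MSE is the Brier score of the predicted positive-class probability;
AUC is the trapezoidal area under the ROC curve.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from sklearn.ensemble import (ExtraTreesClassifier, GradientBoostingClassifier,
                              RandomForestClassifier, StackingClassifier)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ValidationError
from .protocol import CohortTable

__all__ = [
    "ALGORITHMS", "ModelSpec", "ModelScore", "smote", "generate_combinations",
    "count_possible_combinations", "split_cohort", "evaluate_model",
    "run_benchmark", "confusion_metrics",
]

POSITIVE = "dcSSc"
NEGATIVE = "lcSSc"

ALGORITHMS = (
    "logistic_regression", "decision_tree", "random_forest", "linear_svm",
    "rbf_svm", "neural_network", "gbm", "stacked_ensemble", "extra_trees",
    "knn", "xgboost",
)


def _make_estimator(name: str, seed: int):
    if name == "logistic_regression":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "linear_svm":
        return SVC(kernel="linear", probability=True, random_state=seed)
    if name == "rbf_svm":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if name == "neural_network":
        return MLPClassifier(hidden_layer_sizes=(16,), max_iter=500,
                             random_state=seed)
    if name == "gbm":
        return GradientBoostingClassifier(random_state=seed)
    if name == "stacked_ensemble":
        base = [("lr", LogisticRegression(max_iter=1000, random_state=seed)),
                ("rf", RandomForestClassifier(n_estimators=50, random_state=seed)),
                ("gbm", GradientBoostingClassifier(random_state=seed))]
        return StackingClassifier(base, LogisticRegression(max_iter=1000),
                                  cv=3)
    if name == "extra_trees":
        return ExtraTreesClassifier(n_estimators=100, random_state=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "xgboost":
        from xgboost import XGBClassifier
        return XGBClassifier(n_estimators=100, random_state=seed,
                             verbosity=0, eval_metric="logloss")
    raise ValidationError(f"unknown algorithm {name!r}")


@dataclass
class ModelSpec:
    feature_combination: tuple[str, ...]
    algorithm: str
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= len(self.feature_combination) <= 5):
            raise ValidationError("combination size must be 1..5")
        if self.algorithm not in ALGORITHMS:
            raise ValidationError(f"unknown algorithm {self.algorithm!r}")


@dataclass
class ModelScore:
    MSE: float
    LogLoss: float
    Sensitivity: float
    Specificity: float
    Precision: float
    Accuracy: float
    AUC: float
    F1: float
    cv_mean: dict[str, float] = field(default_factory=dict)
    cv_sd: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {"MSE": self.MSE, "LogLoss": self.LogLoss,
                "Sensitivity": self.Sensitivity, "Specificity": self.Specificity,
                "Precision": self.Precision, "Accuracy": self.Accuracy,
                "AUC": self.AUC, "F1": self.F1}


def smote(features: pd.DataFrame, labels: pd.Series, k: int = 5,
          seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Oversample the minority class to parity by neighbor interpolation.

    Each synthetic row is x + u*(x_nn - x) with u ~ Uniform(0,1) and x_nn
    one of x's k nearest minority neighbors (Euclidean). Original rows are
    returned unchanged, synthetic rows appended.
    """
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValidationError("SMOTE requires two classes")
    minority = counts.idxmin()
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return features.copy(), labels.copy()
    Xm = features[labels == minority].to_numpy(dtype=float)
    n_min = Xm.shape[0]
    if n_min < 2:
        raise ValidationError("minority class too small for SMOTE")
    if n_min < k + 1:
        warnings.warn(f"minority class has {n_min} members; reducing k to {n_min - 1}")
        k = n_min - 1
    rng = np.random.default_rng(seed)
    d = np.linalg.norm(Xm[:, None, :] - Xm[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    nn_idx = np.argsort(d, axis=1)[:, :k]
    base = rng.integers(0, n_min, size=n_needed)
    pick = rng.integers(0, k, size=n_needed)
    u = rng.uniform(0, 1, size=n_needed)
    neigh = nn_idx[base, pick]
    synth = Xm[base] + u[:, None] * (Xm[neigh] - Xm[base])
    synth_df = pd.DataFrame(synth, columns=features.columns,
                            index=[f"synthetic_{i}" for i in range(n_needed)])
    out_X = pd.concat([features, synth_df])
    out_y = pd.concat([labels, pd.Series([minority] * n_needed,
                                         index=synth_df.index)])
    return out_X, out_y


def generate_combinations(features, max_size: int = 5) -> list[tuple[str, ...]]:
    """All subsets of sizes 1..max_size in deterministic lexicographic order."""
    feats = sorted(features)
    if not feats:
        raise ValidationError("empty feature set")
    out: list[tuple[str, ...]] = []
    for size in range(1, min(max_size, len(feats)) + 1):
        out.extend(itertools.combinations(feats, size))
    return out


def count_possible_combinations(n: int = 24, max_size: int = 5) -> int:
    """Sum_{i=1..min(max_size,n)} C(n, i)."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    return sum(comb(n, i) for i in range(1, min(max_size, n) + 1))


def split_cohort(features: pd.DataFrame, labels: pd.Series,
                 train_frac: float = 0.8, seed: int = 0):
    """Stratified train/validation split."""
    if labels.value_counts().min() < 2:
        raise ValidationError("each class needs >= 2 members to split")
    X_tr, X_va, y_tr, y_va = train_test_split(
        features, labels, train_size=train_frac, stratify=labels,
        random_state=seed)
    return X_tr, X_va, y_tr, y_va


def confusion_metrics(y_true: np.ndarray, prob_pos: np.ndarray,
                      threshold: float = 0.5) -> dict[str, float]:
    """The 8 performance metrics from labels (1 = positive) and predicted
    positive-class probabilities."""
    y_true = np.asarray(y_true, dtype=int)
    prob = np.clip(np.asarray(prob_pos, dtype=float), 1e-12, 1 - 1e-12)
    pred = (prob >= threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else math.nan
    spec = tn / (tn + fp) if tn + fp else math.nan
    prec = tp / (tp + fp) if tp + fp else math.nan
    acc = (tp + tn) / y_true.size
    f1 = (2 * prec * sens / (prec + sens)
          if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
          else math.nan)
    auc = (float(roc_auc_score(y_true, prob))
           if len(np.unique(y_true)) == 2 else math.nan)
    return {"MSE": float(np.mean((prob - y_true) ** 2)),
            "LogLoss": float(log_loss(y_true, prob, labels=[0, 1])),
            "Sensitivity": sens, "Specificity": spec, "Precision": prec,
            "Accuracy": acc, "AUC": auc, "F1": f1}


def _prob_pos(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    warnings.warn(f"{type(model).__name__} has no predict_proba; "
                  "using min-max calibrated decision scores")
    score = model.decision_function(X)
    lo, hi = score.min(), score.max()
    return (score - lo) / (hi - lo) if hi > lo else np.full(score.shape, 0.5)


def evaluate_model(spec: ModelSpec, train: tuple[pd.DataFrame, pd.Series],
                   validation: tuple[pd.DataFrame, pd.Series],
                   cv_k: int = 5, cv_repeats: int = 10,
                   smote_policy: str = "within_folds") -> ModelScore:
    """Fit one (combination, algorithm) cell and score it.

    Held-out metrics come from a model fitted on the (SMOTE-balanced)
    training set and applied to the untouched validation set; CV mean/sd
    per metric come from repeated stratified k-fold on the training set
    (skipped when cv_repeats == 0).
    """
    cols = list(spec.feature_combination)
    X_tr = train[0][cols]
    y_tr = (train[1] == POSITIVE).astype(int)
    X_va = validation[0][cols].to_numpy(dtype=float)
    y_va = (validation[1] == POSITIVE).astype(int).to_numpy()

    def fit_once(X: pd.DataFrame, y: pd.Series):
        if smote_policy in ("within_folds", "before_split"):
            Xb, yb = smote(X, y.map({1: POSITIVE, 0: NEGATIVE}), seed=spec.seed)
            yb = (yb == POSITIVE).astype(int)
        else:
            Xb, yb = X, y
        model = _make_estimator(spec.algorithm, spec.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xb.to_numpy(dtype=float), yb.to_numpy())
        return model

    model = fit_once(X_tr, y_tr)
    held_out = confusion_metrics(y_va, _prob_pos(model, X_va))

    cv_mean: dict[str, float] = {}
    cv_sd: dict[str, float] = {}
    if cv_repeats > 0:
        splitter = RepeatedStratifiedKFold(n_splits=cv_k, n_repeats=cv_repeats,
                                           random_state=spec.seed)
        fold_scores: list[dict[str, float]] = []
        Xt = X_tr.reset_index(drop=True)
        yt = y_tr.reset_index(drop=True)
        for tr_idx, te_idx in splitter.split(Xt, yt):
            m = fit_once(Xt.iloc[tr_idx], yt.iloc[tr_idx])
            probs = _prob_pos(m, Xt.iloc[te_idx].to_numpy(dtype=float))
            fold_scores.append(confusion_metrics(yt.iloc[te_idx].to_numpy(), probs))
        frame = pd.DataFrame(fold_scores)
        cv_mean = frame.mean().to_dict()
        cv_sd = frame.std(ddof=1).to_dict()
    return ModelScore(**held_out, cv_mean=cv_mean, cv_sd=cv_sd)


def run_benchmark(cohort: CohortTable, selected_features: list[str],
                  seed: int = 0, cv_k: int = 5, cv_repeats: int = 10,
                  smote_policy: str = "within_folds",
                  algorithms: tuple[str, ...] = ALGORITHMS
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate every (combination x algorithm) cell.

    Returns (report, grid): `grid` holds every cell; `report` keeps, per
    combination, the best algorithm by held-out F1 (grouped by combination
    size). Failed cells are logged in the grid with NaN metrics.
    """
    combos = generate_combinations(selected_features)
    feats = cohort.features[selected_features]
    labels = cohort.labels
    cell_policy = smote_policy
    if smote_policy == "before_split":
        # balance the full table first (leakage-prone order, kept for parity
        # with the simpler protocol), then never re-balance inside cells
        feats, labels = smote(feats, labels, seed=seed)
        cell_policy = "none"
    X_tr, X_va, y_tr, y_va = split_cohort(feats, labels, seed=seed)
    smote_policy = cell_policy
    rows = []
    for combo in combos:
        for algo in algorithms:
            spec = ModelSpec(combo, algo, seed=seed)
            entry = {"variables": ", ".join(combo), "n_variables": len(combo),
                     "algorithm": algo}
            try:
                score = evaluate_model(spec, (X_tr, y_tr), (X_va, y_va),
                                       cv_k=cv_k, cv_repeats=cv_repeats,
                                       smote_policy=smote_policy)
                entry.update(score.as_dict())
                for k, v in score.cv_mean.items():
                    entry[f"cv_{k}_mean"] = v
                for k, v in score.cv_sd.items():
                    entry[f"cv_{k}_sd"] = v
            except Exception as exc:  # keep the grid going
                warnings.warn(f"cell ({combo}, {algo}) failed: {exc}")
                entry["error"] = str(exc)
            rows.append(entry)
    grid = pd.DataFrame(rows)
    scored = grid.dropna(subset=["F1"]) if "F1" in grid else grid.iloc[0:0]
    best = (scored.sort_values(["F1", "AUC"], ascending=False, kind="mergesort")
            .groupby("variables", as_index=False, sort=False).head(1)
            .sort_values(["n_variables", "F1"], ascending=[True, False],
                         kind="mergesort").reset_index(drop=True))
    return best, grid
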
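"""Descriptive statistics for the cohort table.

Univariate group comparisons are normality-gated (Shapiro-Wilk at 0.05 in
both groups -> Welch t-test, otherwise Mann-Whitney U); categorical tables
use Fisher's exact test when a 2x2 expected cell falls below 5, chi-square
otherwise. The group-by-position analysis is a two-way mixed (split-plot)
ANOVA with the clinical form between subjects and the position within
subjects, Bonferroni-corrected across the three effects per variable; when
the residuals fail normality the Scheirer-Ray-Hare rank-based factorial
(reporting H statistics) is used instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .protocol import CohortTable, METRIC_REGISTRY

__all__ = [
    "TestResult",
    "AnovaResult",
    "univariate_compare",
    "categorical_compare",
    "mixed_anova",
    "scheirer_ray_hare",
    "correlation_matrix",
    "group_position_report",
]


@dataclass
class TestResult:
    variable: str
    test_name: str
    statistic: float
    df: float | None
    p_unadjusted: float
    p_adjusted: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_adjusted < alpha


@dataclass
class AnovaResult:
    variable: str
    effect: str  # clinical_form | position | interaction
    test_name: str  # mixed_anova (F) or scheirer_ray_hare (H)
    statistic: float
    p_adjusted: float


def _groups(cohort: CohortTable, variable: str) -> tuple[np.ndarray, np.ndarray]:
    x = cohort.frame.loc[cohort.labels == "dcSSc", variable].to_numpy(float)
    y = cohort.frame.loc[cohort.labels == "lcSSc", variable].to_numpy(float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size < 3 or y.size < 3:
        raise InsufficientDataError(f"{variable}: need >= 3 observations per group")
    return x, y


def _is_normal(sample: np.ndarray, alpha: float = 0.05) -> bool:
    if np.ptp(sample) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.shapiro(sample).pvalue >= alpha


def univariate_compare(cohort: CohortTable, variable: str) -> TestResult:
    """Welch t-test when both groups pass Shapiro-Wilk, else Mann-Whitney U."""
    x, y = _groups(cohort, variable)
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValidationError(f"{variable}: zero variance in both groups")
    if _is_normal(x) and _is_normal(y):
        res = stats.ttest_ind(x, y, equal_var=False)
        return TestResult(variable, "welch_t", float(res.statistic),
                          float(res.df), float(res.pvalue), float(res.pvalue))
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult(variable, "mann_whitney_u", float(res.statistic), None,
                      float(res.pvalue), float(res.pvalue))


def categorical_compare(table, variable: str = "") -> TestResult:
    """Fisher exact (2x2 with small expected counts) or chi-square test."""
    tab = np.asarray(table, dtype=float)
    if tab.min() < 0 or not np.allclose(tab, np.round(tab)):
        raise ValidationError("contingency table needs non-negative integer counts")
    if tab.sum() == 0:
        raise ValidationError("all-zero contingency table")
    rows = tab.sum(axis=1, keepdims=True)
    cols = tab.sum(axis=0, keepdims=True)
    expected = rows @ cols / tab.sum()
    if tab.shape == (2, 2) and (expected <= 5).any():
        stat, p = stats.fisher_exact(tab.astype(int))
        return TestResult(variable, "fisher_exact", float(stat), None,
                          float(p), float(p))
    chi2, p, dof, _ = stats.chi2_contingency(tab)
    return TestResult(variable, "chi_square", float(chi2), float(dof),
                      float(p), float(p))


def _long_frame(cohort: CohortTable, metric: str) -> pd.DataFrame:
    rows = []
    for sid, row in cohort.frame.iterrows():
        for pos in ("S1", "S2"):
            rows.append({"subject": sid, "group": row["group"], "position": pos,
                         "value": float(row[f"{metric}_{pos}"])})
    df = pd.DataFrame(rows)
    # listwise exclusion of subjects missing either position
    ok = df.groupby("subject")["value"].transform(lambda v: np.isfinite(v).all())
    dropped = df.loc[~ok, "subject"].unique()
    if dropped.size:
        warnings.warn(f"{metric}: excluding subjects with missing values: "
                      f"{sorted(dropped)[:5]}")
    return df[ok]


def scheirer_ray_hare(df: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Rank-based two-factor ANOVA extension of Kruskal-Wallis.

    Expects columns group, position, value. Returns {effect: (H, p)} with
    the H statistics referred to chi-square distributions.
    """
    d = df.copy()
    d["rank"] = stats.rankdata(d["value"])
    ms_total = d["rank"].var(ddof=1)  # rank variance, ties-corrected by construction
    grand = d["rank"].mean()

    def ss(groupby) -> float:
        g = d.groupby(groupby, observed=True)["rank"]
        return float((g.count() * (g.mean() - grand) ** 2).sum())

    ss_a = ss("group")
    ss_b = ss("position")
    ss_cells = ss(["group", "position"])
    ss_ab = ss_cells - ss_a - ss_b
    out = {}
    for effect, ssq, dof in (("clinical_form", ss_a, 1), ("position", ss_b, 1),
                             ("interaction", ss_ab, 1)):
        h = ssq / ms_total
        out[effect] = (h, float(stats.chi2.sf(max(h, 0.0), dof)))
    return out


def mixed_anova(cohort: CohortTable, metric: str,
                bonferroni: int = 3) -> list[AnovaResult]:
    """Group (between) x position (within) factorial for one metric.

    Uses a parametric mixed ANOVA when the cell residuals pass Shapiro-Wilk,
    otherwise the Scheirer-Ray-Hare rank test. p-values are Bonferroni
    multiplied by ``bonferroni`` and capped at 1.
    """
    df = _long_frame(cohort, metric)
    for g in ("dcSSc", "lcSSc"):
        if df.loc[df.group == g, "subject"].nunique() < 3:
            raise InsufficientDataError(f"{metric}: fewer than 3 {g} subjects")
    resid = df["value"] - df.groupby(["group", "position"], observed=True
                                     )["value"].transform("mean")
    effects: dict[str, tuple[float, float]]
    if _is_normal(resid.to_numpy()):
        import pingouin as pg
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = pg.mixed_anova(data=df, dv="value", within="position",
                                 between="group", subject="subject")
        name_map = {"group": "clinical_form", "position": "position",
                    "Interaction": "interaction"}
        effects = {}
        for _, r in aov.iterrows():
            eff = name_map.get(str(r["Source"]))
            if eff:
                effects[eff] = (float(r["F"]), float(r["p_unc"]))
        test_name = "mixed_anova"
    else:
        effects = scheirer_ray_hare(df)
        test_name = "scheirer_ray_hare"
    return [AnovaResult(metric, eff, test_name, stat,
                        min(1.0, p * bonferroni))
            for eff, (stat, p) in effects.items()]


def correlation_matrix(cohort: CohortTable, variables: list[str],
                       alpha: float = 0.05
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise correlations: Pearson when both normal, else Spearman.

    Returns (R, p) DataFrames; R entries with p >= alpha are masked to NaN
    (diagonal kept at 1).
    """
    data = cohort.frame[variables].astype(float)
    if len(data) < 4:
        raise InsufficientDataError("need >= 4 paired observations")
    normal = {v: _is_normal(data[v].to_numpy()) for v in variables}
    k = len(variables)
    R = np.eye(k)
    P = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = data.iloc[:, i].to_numpy(), data.iloc[:, j].to_numpy()
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                warnings.warn(f"constant column in pair ({variables[i]}, {variables[j]})")
                r, p = math.nan, math.nan
            elif normal[variables[i]] and normal[variables[j]]:
                r, p = stats.pearsonr(xi, xj)
            else:
                res = stats.spearmanr(xi, xj)
                r, p = float(res.statistic), float(res.pvalue)
            R[i, j] = R[j, i] = r
            P[i, j] = P[j, i] = p
    Rm = pd.DataFrame(R, index=variables, columns=variables)
    Pm = pd.DataFrame(P, index=variables, columns=variables)
    masked = Rm.where((Pm < alpha) | np.eye(k, dtype=bool))
    return masked, Pm


def group_position_report(cohort: CohortTable) -> pd.DataFrame:
    """Group x position means +/- SD with the three factorial effect p-values
    and a Welch comparison of the per-subject stand-up deltas per metric."""
    rows = []
    for metric in METRIC_REGISTRY:
        entry: dict[str, float | str] = {"metric": metric}
        for pos in ("S1", "S2", "delta"):
            col = f"{metric}_{pos}"
            for grp in ("dcSSc", "lcSSc"):
                vals = cohort.frame.loc[cohort.labels == grp, col].astype(float)
                entry[f"{grp}_{pos}_mean"] = float(vals.mean())
                entry[f"{grp}_{pos}_sd"] = float(vals.std(ddof=1))
        try:
            for res in mixed_anova(cohort, metric):
                entry[f"p_{res.effect}"] = res.p_adjusted
                entry["factorial_test"] = res.test_name
        except InsufficientDataError:
            pass
        try:
            delta = univariate_compare(cohort, f"{metric}_delta")
            entry["p_delta"] = delta.p_unadjusted
            entry["delta_test"] = delta.test_name
        except (InsufficientDataError, ValidationError):
            pass
        rows.append(entry)
    return pd.DataFrame(rows).set_index("metric")
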
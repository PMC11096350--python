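"""Per-subject assembly: S1/S2 metric vectors, stand-up deltas, cohort table.

The feature registry fixes 29 metrics (7 time-domain, 10 frequency-domain,
12 nonlinear) and the `{metric}_{S1|S2|delta}` column naming, giving the
87-feature cohort table (+ group label) used by the statistics and
classification stages. Lmin and DIV are computed by the RQA operation but
excluded from the feature registry: with minimum line length 2 Lmin is the
constant 2 on physiological segments (zero variance) and DIV is exactly
1/Lmax.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import HrvpcError, PipelineError
from .hrv_linear import frequency_domain_metrics, time_domain_metrics
from .hrv_nonlinear import EmbeddingConfig, apen, cordim, dfa, poincare, rqa, sampen
from .preprocess import CorrectionReport, correct_artifacts
from .signal_io import CohortManifest, RriSeries, read_rri

logger = logging.getLogger(__name__)

__all__ = [
    "TIME_METRICS", "FREQ_METRICS", "NONLINEAR_METRICS", "METRIC_REGISTRY",
    "FEATURE_COLUMNS", "HrvVector", "SubjectRecord", "CohortTable",
    "compute_hrv_vector", "stand_up_features", "build_cohort",
]

TIME_METRICS = ("mean_RR", "sd_RR", "mean_HR", "sd_HR", "RMSSD", "NN50", "pNN50")
FREQ_METRICS = ("LF_peak", "HF_peak", "LF_power", "LF_power_prc", "LF_power_nu",
                "HF_power", "HF_power_prc", "HF_power_nu", "LF_HF_power",
                "tot_power")
NONLINEAR_METRICS = ("SD1", "SD2", "ApEn", "SampEn", "alpha1", "alpha2",
                     "CorDim", "Lmax", "Lmean", "REC", "DET", "ShanEn")
METRIC_REGISTRY: tuple[str, ...] = TIME_METRICS + FREQ_METRICS + NONLINEAR_METRICS

FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"{m}_{cond}" for cond in ("S1", "S2", "delta") for m in METRIC_REGISTRY)


class HrvVector(dict):
    """Named metric set for one 5-min segment (keys = METRIC_REGISTRY)."""

    def __init__(self, values: dict[str, float]):
        missing = set(METRIC_REGISTRY) - set(values)
        if missing:
            raise HrvpcError(f"HrvVector missing metrics: {sorted(missing)}")
        super().__init__({k: float(values[k]) for k in METRIC_REGISTRY})


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    hrv_S1: HrvVector
    hrv_S2: HrvVector
    hrv_delta: HrvVector
    correction_reports: dict[str, CorrectionReport] = field(default_factory=dict)


@dataclass
class CohortTable:
    """Rows = subjects, columns = FEATURE_COLUMNS + 'group'."""

    frame: pd.DataFrame
    exclusions: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = list(FEATURE_COLUMNS) + ["group"]
        missing = [c for c in expected if c not in self.frame.columns]
        if missing:
            raise HrvpcError(f"cohort table missing columns: {missing[:5]}...")
        self.frame = self.frame[expected]

    @property
    def features(self) -> pd.DataFrame:
        return self.frame[list(FEATURE_COLUMNS)]

    @property
    def labels(self) -> pd.Series:
        return self.frame["group"]


def compute_hrv_vector(rri: RriSeries) -> HrvVector:
    """All 29 registry metrics for one corrected segment."""
    values: dict[str, float] = {}
    values.update(time_domain_metrics(rri).as_dict())
    values.update(frequency_domain_metrics(rri).as_dict())
    pc = poincare(rri)
    values["SD1"], values["SD2"] = pc.SD1, pc.SD2
    a1, a2 = dfa(rri)
    values["alpha1"], values["alpha2"] = a1, a2
    values["ApEn"] = apen(rri)
    values["SampEn"] = sampen(rri)
    values["CorDim"] = cordim(rri)
    rq = rqa(rri, EmbeddingConfig(m=10, tau=1))
    values["Lmax"], values["Lmean"] = rq.Lmax, rq.Lmean
    values["REC"], values["DET"], values["ShanEn"] = rq.REC, rq.DET, rq.ShanEn
    return HrvVector(values)


def stand_up_features(s1: RriSeries, s2: RriSeries
                      ) -> tuple[HrvVector, HrvVector, HrvVector]:
    """Metric vectors for both positions plus the S2 - S1 delta vector."""
    try:
        v1 = compute_hrv_vector(s1)
    except HrvpcError as exc:
        raise PipelineError(f"segment S1: {exc}") from exc
    try:
        v2 = compute_hrv_vector(s2)
    except HrvpcError as exc:
        raise PipelineError(f"segment S2: {exc}") from exc
    delta = HrvVector({k: v2[k] - v1[k] for k in METRIC_REGISTRY})
    return v1, v2, delta


def _subject_record(sid: str, group: str, s1: RriSeries, s2: RriSeries,
                    correct: bool) -> SubjectRecord:
    reports: dict[str, CorrectionReport] = {}
    if correct:
        s1, reports["S1"] = correct_artifacts(s1)
        s2, reports["S2"] = correct_artifacts(s2)
    v1, v2, delta = stand_up_features(s1, s2)
    return SubjectRecord(sid, group, v1, v2, delta, reports)


def records_to_table(records: list[SubjectRecord],
                     exclusions: list[dict] | None = None) -> CohortTable:
    rows = []
    for rec in records:
        row: dict[str, float | str] = {"group": rec.group}
        for cond, vec in (("S1", rec.hrv_S1), ("S2", rec.hrv_S2),
                          ("delta", rec.hrv_delta)):
            for m in METRIC_REGISTRY:
                row[f"{m}_{cond}"] = vec[m]
        rows.append(pd.Series(row, name=rec.subject_id))
    if not rows:
        raise PipelineError("empty cohort after exclusions")
    return CohortTable(pd.DataFrame(rows), exclusions or [])


def build_cohort(manifest: CohortManifest, correct: bool = True) -> CohortTable:
    """One feature row per manifest subject; failures become exclusions."""
    records: list[SubjectRecord] = []
    exclusions: list[dict] = []
    for _, row in manifest.rows.iterrows():
        sid = str(row["subject_id"])
        try:
            if row["input_kind"] == "ecg":
                from .qrs_detect import ecg_to_rri
                from .signal_io import read_ecg_csv
                s1 = ecg_to_rri(read_ecg_csv(row["path_S1"]))
                s2 = ecg_to_rri(read_ecg_csv(row["path_S2"]))
            else:
                s1 = read_rri(row["path_S1"])
                s2 = read_rri(row["path_S2"])
            records.append(_subject_record(sid, row["group"], s1, s2, correct))
        except (HrvpcError, OSError) as exc:
            logger.warning("excluding subject %s: %s", sid, exc)
            exclusions.append({"subject_id": sid, "reason": str(exc)})
    return records_to_table(records, exclusions)


def build_cohort_from_series(series: dict[tuple[str, str], RriSeries],
                             groups: dict[str, str],
                             correct: bool = False) -> CohortTable:
    """In-memory variant of build_cohort for generated cohorts."""
    records: list[SubjectRecord] = []
    exclusions: list[dict] = []
    for sid, group in groups.items():
        try:
            records.append(_subject_record(
                sid, group, series[(sid, "S1")], series[(sid, "S2")], correct))
        except HrvpcError as exc:
            logger.warning("excluding subject %s: %s", sid, exc)
            exclusions.append({"subject_id": sid, "reason": str(exc)})
    return records_to_table(records, exclusions)
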
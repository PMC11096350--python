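"""End-to-end orchestration: simulate/ingest -> cohort -> stats -> features
-> benchmark, from a single validated config with one global seed.

Stage seeds are derived deterministically from the global seed via a
spawned numpy SeedSequence-backed generator, so any stage can be re-run in
isolation and the whole run is idempotent at a fixed config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PipelineError, ValidationError
from . import __version__
from .cohort_stats import group_position_report
from .feature_engineering import (gamma_rank, prune_collinear, rank_features,
                                  screen_univariate, select_top)
from .model_bench import run_benchmark
from .protocol import build_cohort, CohortTable
from .signal_io import read_cohort_manifest
from .synthetic_data import default_preset, make_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "stage_seeds"]

_KNOWN_KEYS = {"seed", "out_dir", "manifest", "simulate", "n_top", "screen_p",
               "r2_threshold", "cv_repeats", "smote_policy", "arbiter"}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "hrvpc_run"
    manifest: str | None = None     # path to an existing cohort manifest CSV
    simulate: bool = True           # generate the synthetic cohort when no manifest
    n_top: int = 5
    screen_p: float = 0.1
    r2_threshold: float = 0.9
    cv_repeats: int = 10
    smote_policy: str = "within_folds"
    arbiter: list[str] = field(default_factory=list)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def stage_seeds(seed: int, stages: tuple[str, ...] = (
        "simulate", "cohort", "features", "bench")) -> dict[str, int]:
    """Deterministic per-stage seeds derived from the global seed."""
    rng = np.random.default_rng(seed)
    return {name: int(rng.integers(2 ** 31)) for name in stages}


def run_all(config: PipelineConfig) -> Path:
    """Run the whole pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)

    def fail(stage: str, exc: Exception):
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- cohort ---------------------------------------------------------
    try:
        if config.manifest is not None:
            manifest = read_cohort_manifest(config.manifest)
        elif config.simulate:
            manifest, _ = make_cohort(default_preset(), seed=seeds["simulate"],
                                      out_dir=out / "synth")
        else:
            raise ValidationError("config needs a manifest or simulate=true")
    except (OSError, ValidationError) as exc:
        fail("cohort", exc)
    try:
        cohort = build_cohort(manifest)
    except Exception as exc:
        fail("cohort", exc)
    cohort.frame.to_csv(out / "cohort_features.csv")
    (out / "exclusions.json").write_text(json.dumps(cohort.exclusions, indent=2))

    # --- stats ----------------------------------------------------------
    try:
        stats_report = group_position_report(cohort)
    except Exception as exc:
        fail("stats", exc)
    stats_report.to_csv(out / "stats_report.csv")

    # --- features -------------------------------------------------------
    try:
        screened = screen_univariate(cohort, alpha=config.screen_p)
        pruned, removal_log = prune_collinear(cohort, screened,
                                              config.r2_threshold)
        ranks = rank_features(cohort, pruned, seed=seeds["features"])
        gammas = gamma_rank(cohort, list(ranks.index))
        selected, sel_info = select_top(ranks, gammas, n_top=config.n_top,
                                        arbiter=config.arbiter or None)
    except Exception as exc:
        fail("features", exc)
    ranks.to_csv(out / "ranks.csv")
    (out / "selection.json").write_text(json.dumps(
        {"selected": selected, **sel_info, "removed": removal_log}, indent=2))

    # --- benchmark ------------------------------------------------------
    try:
        report, grid = run_benchmark(cohort, selected, seed=seeds["bench"],
                                     cv_repeats=config.cv_repeats,
                                     smote_policy=config.smote_policy)
    except Exception as exc:
        fail("bench", exc)
    report.to_csv(out / "benchmark_report.csv", index=False)
    grid.to_csv(out / "benchmark_grid.csv", index=False)

    provenance = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()).hexdigest(),
        "stage_seeds": seeds,
        "n_subjects": int(len(cohort.frame)),
        "selected_features": selected,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out
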
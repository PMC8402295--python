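"""End-to-end tri-stage pipeline: preprocess, rank, screen, prune, optimize.

Produces a JSON-serializable report with every stage's artifact. The report
is a pure function of (dataset, config): identical seeds give identical
reports byte for byte. Per-stage wall-clock timing goes to the logger, not
into the report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import data_io, filters, stage1, stage2, woa
from .data_io import Dataset

log = logging.getLogger("tristage")

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters plus the master seed.

    ``m`` defaults to a width-scaled value (see :func:`stage1.default_m`).
    The master seed drives every stochastic component: fold assignments,
    ReliefF sampling, XGBoost, and the WOA restarts.
    """

    m: int | None = None
    n_bins: int = 10
    relieff_k: int = 10
    coarse_step: int = 5
    cv_folds: int = 10
    pcc_threshold: float = 0.7
    woa: woa.WOAConfig = field(default_factory=woa.WOAConfig)
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        cfg = asdict(self)
        cfg["seed"] = seed
        cfg["woa"]["seed"] = seed
        return PipelineConfig.from_dict(cfg)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        woa_cfg = payload.pop("woa", {})
        return cls(woa=woa.WOAConfig(**woa_cfg), **payload)


def _names(d: Dataset, indices) -> list:
    return [str(d.feature_names[int(i)]) for i in indices]


def run_pipeline(d: Dataset, config: PipelineConfig | None = None) -> dict:
    """Execute the full tri-stage selection and return the report dict."""
    config = config or PipelineConfig()
    m = config.m if config.m is not None else stage1.default_m(d.n_features)
    if m > d.n_features:
        raise ValueError(f"m={m} exceeds feature count {d.n_features}")
    classes, counts = np.unique(d.labels, return_counts=True)
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"smallest class ({counts.min()}) cannot support {config.cv_folds} folds"
        )
    relieff_k = min(config.relieff_k, int(counts.min()) - 1)
    seed = int(config.seed)

    t0 = time.perf_counter()
    d = data_io.preprocess(d)
    log.info("preprocess: %d samples x %d features (%.2fs)", d.n_samples, d.n_features,
             time.perf_counter() - t0)

    t0 = time.perf_counter()
    ranked = filters.rank_all(d, n_bins=config.n_bins, relieff_k=relieff_k, seed=seed)
    log.info("filters: 4 rankings (%.2fs)", time.perf_counter() - t0)

    pool = stage1.union_top_m(ranked.values(), m)
    log.info("union: m=%d -> %d pooled features", m, pool.size)

    t0 = time.perf_counter()
    records = stage1.score_features_individually(
        d, pool, cv_folds=config.cv_folds, seed=seed
    )
    ordered = stage1.sort_by_mean_accuracy(records)
    log.info("stage1 screening: %d features scored (%.2fs)", pool.size,
             time.perf_counter() - t0)

    t0 = time.perf_counter()
    s1 = stage1.plateau_select(
        d, ordered, coarse_step=config.coarse_step, cv_folds=config.cv_folds, seed=seed
    )
    log.info("stage1 plateau: k=%d (%.2fs)", s1.selected_size, time.perf_counter() - t0)

    t0 = time.perf_counter()
    if s1.selected_size >= 2:
        cm = stage2.correlation_matrix(d, s1.selected_features)
        pruned = stage2.prune_correlated(cm, config.pcc_threshold)
        s2 = stage2.select_top_j(
            d,
            pruned.kept,
            coarse_step=config.coarse_step,
            cv_folds=config.cv_folds,
            seed=seed,
        )
    else:
        pruned = stage2.PruneResult(s1.selected_features, [])
        s2 = stage1.StageResult(s1.selected_features, 1, {1: max(s1.prefix_accuracy_trace.values())})
    log.info("stage2: %d kept, j=%d (%.2fs)", pruned.kept.size, s2.selected_size,
             time.perf_counter() - t0)

    t0 = time.perf_counter()
    woa_cfg = woa.WOAConfig(**{**asdict(config.woa), "seed": seed})
    summary = woa.run_woa_repeated(d, s2.selected_features, woa_cfg)
    log.info("woa: %d runs, mean acc %.4f, mean size %.2f (%.2fs)", woa_cfg.n_runs,
             summary.mean_accuracy, summary.mean_size, time.perf_counter() - t0)

    mean_accs = {r.feature_index: r.mean_accuracy for r in records}
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": {**asdict(config), "m": int(m), "relieff_k": relieff_k},
        "dataset": {
            "n_samples": int(d.n_samples),
            "n_features": int(d.n_features),
            "classes": [str(c) for c in classes],
            "class_counts": [int(c) for c in counts],
        },
        "filters": {
            name: _names(d, rl.top(m)) for name, rl in ranked.items()
        },
        "union": {"m": int(m), "size": int(pool.size), "features": _names(d, pool)},
        "stage1": {
            **s1.to_dict(d.feature_names),
            "mean_accuracy": {
                str(d.feature_names[i]): mean_accs[int(i)] for i in ordered
            },
        },
        "stage2": {
            "prune": (
                stage2.PruneResult(pruned.kept, pruned.discarded).to_dict(d.feature_names)
            ),
            **s2.to_dict(d.feature_names),
        },
        "woa": {
            "runs": [
                {
                    "features": _names(d, run.selected(s2.selected_features)),
                    "accuracy": run.accuracy,
                    "size": int(run.size),
                    "fitness": run.fitness,
                }
                for run in summary.runs
            ],
            "mean_accuracy": summary.mean_accuracy,
            "mean_size": summary.mean_size,
        },
    }
    best = min(summary.runs, key=lambda r: r.fitness)
    report["final"] = {
        "mean_accuracy": summary.mean_accuracy,
        "mean_size": summary.mean_size,
        "best_features": _names(d, best.selected(s2.selected_features)),
        "best_accuracy": best.accuracy,
        "best_size": int(best.size),
    }
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
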
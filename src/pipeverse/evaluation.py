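"""Ground-truth evaluation of the multiverse and of the guided search.

Provides exhaustive (empirical) landscapes, agreement between estimated and
empirical landscapes (Spearman rank correlation), optima extraction from a
search trace, repeated-run reliability reports, lock-box hold-out scoring,
and a synthetic benchmark landscape with a known optimum for validating the
search loop itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mean_absolute_error, roc_auc_score

from .pipelines import PipelineCache, PipelineGrid, PipelineSpec, apply_pipeline, build_grid, features_matrix
from .search import (
    LandscapeEstimate,
    Score,
    SearchConfig,
    SearchTrace,
    _make_estimator,
    evaluate_pipeline,
    predict_landscape,
    run_search,
)
from .space import EmbeddedSpace
from .synthetic_data import SubjectDataset

logger = logging.getLogger(__name__)


@dataclass
class EmpiricalLandscape:
    """One cross-validated score per pipeline over the full grid."""

    scores: np.ndarray
    objective: str
    pipeline_ids: np.ndarray

    def argmax(self) -> int:
        return int(np.argmax(self.scores))


@dataclass
class RepetitionReport:
    """Per-repetition optima, hold-out scores and landscape agreement."""

    rows: pd.DataFrame
    n_reps: int
    failures: list[tuple[int, str]]


def exhaustive_evaluate(
    dataset: SubjectDataset | None,
    grid: PipelineGrid,
    config: SearchConfig,
    cache: PipelineCache | None = None,
    evaluator=None,
) -> EmpiricalLandscape:
    """Score every pipeline in the grid.

    Uses the same per-pipeline CV seeding as the search loop, so a pipeline's
    empirical score is identical to the score any trace records for it.
    """
    if len(grid) == 0:
        raise ValueError("grid is empty")
    cache = cache if cache is not None else PipelineCache()
    scores = np.empty(len(grid))
    for spec in grid:
        try:
            if evaluator is not None:
                scores[spec.id] = evaluator(spec).value
            else:
                scores[spec.id] = evaluate_pipeline(dataset, spec, config, cache=cache).value
        except Exception as exc:
            raise RuntimeError(f"pipeline {spec.id} ({spec.as_dict()}) failed") from exc
    return EmpiricalLandscape(
        scores=scores, objective=config.objective, pipeline_ids=np.arange(len(grid))
    )


def space_correlation(
    estimate: LandscapeEstimate, empirical: EmpiricalLandscape
) -> float:
    """Spearman rank correlation between the GP posterior mean and the
    empirical scores (ties mid-ranked); NaN when either vector is constant."""
    if len(estimate.mu) != len(empirical.scores):
        raise ValueError("estimate and empirical landscape cover different pipeline sets")
    if np.ptp(estimate.mu) == 0 or np.ptp(empirical.scores) == 0:
        logger.warning("constant landscape vector; Spearman rho undefined")
        return float("nan")
    rho, _ = stats.spearmanr(estimate.mu, empirical.scores)
    return float(rho)


def extract_optima(
    trace: SearchTrace, space: EmbeddedSpace
) -> tuple[int, int]:
    """(gp_optimum, sampled_optimum) pipeline ids.

    The GP optimum maximizes the posterior mean over *all* pipelines; the
    sampled optimum maximizes the observed score.  Ties break by pipeline id.
    """
    if not trace.entries:
        raise ValueError("trace is empty")
    if trace.gp is None:
        raise ValueError("trace has no fitted GP")
    landscape = predict_landscape(trace.gp, space)
    gp_opt = int(np.argmax(landscape.mu))
    sampled_opt = int(trace.pipeline_ids[np.argmax(trace.scores)])
    return gp_opt, sampled_opt


def holdout_score(
    dataset: SubjectDataset,
    spec: PipelineSpec,
    config: SearchConfig,
    cache: PipelineCache | None = None,
) -> float:
    """Lock-box evaluation: refit the estimator on the entire search split and
    score the selected pipeline once on the untouched hold-out split."""
    cache = cache if cache is not None else PipelineCache()
    train_idx = dataset.split_indices("search")
    test_idx = dataset.split_indices("holdout")
    if len(test_idx) == 0:
        raise ValueError("hold-out split is empty")
    y_train = dataset.targets[train_idx]
    y_test = dataset.targets[test_idx]
    if config.objective == "auc" and len(np.unique(y_test)) < 2:
        raise ValueError("hold-out split must contain both classes for AUC")
    X_train = features_matrix(
        apply_pipeline(dataset, spec, subjects=train_idx, cache=cache, seed=config.seed)
    )
    X_test = features_matrix(
        apply_pipeline(dataset, spec, subjects=test_idx, cache=cache, seed=config.seed)
    )
    est = _make_estimator(config)
    est.fit(X_train, y_train)
    if config.objective == "neg_mae":
        return float(-mean_absolute_error(y_test, est.predict(X_test)))
    return float(roc_auc_score(y_test, est.decision_function(X_test)))


def repeat_search(
    dataset: SubjectDataset | None,
    grid: PipelineGrid,
    space: EmbeddedSpace,
    config: SearchConfig,
    n_reps: int = 20,
    base_seed: int = 0,
    cache: PipelineCache | None = None,
    evaluator=None,
    empirical: EmpiricalLandscape | None = None,
    score_holdout: bool = True,
) -> RepetitionReport:
    """Repeat the search with seeds base_seed + r (guaranteed distinct
    burn-ins) and report per-repetition optima, hold-out scores and the
    agreement between the estimated and empirical landscapes.

    Failed repetitions are reported, not silently dropped.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if empirical is None:
        empirical = exhaustive_evaluate(dataset, grid, config, cache=cache, evaluator=evaluator)
    cache = cache if cache is not None else PipelineCache()
    records = []
    failures: list[tuple[int, str]] = []
    for r in range(n_reps):
        rep_config = replace(config, seed=base_seed + r)
        try:
            trace = run_search(dataset, grid, space, rep_config, cache=cache, evaluator=evaluator)
            gp_opt, sampled_opt = extract_optima(trace, space)
            rho = space_correlation(predict_landscape(trace.gp, space), empirical)
            hold = (
                holdout_score(dataset, grid[sampled_opt], rep_config, cache=cache)
                if (score_holdout and dataset is not None and dataset.split is not None)
                else float("nan")
            )
            records.append(
                {
                    "rep": r,
                    "seed": base_seed + r,
                    "gp_optimum": gp_opt,
                    "sampled_optimum": sampled_opt,
                    "sampled_optimum_score": float(trace.scores.max()),
                    "holdout_score": hold,
                    "spearman_rho": rho,
                }
            )
        except Exception as exc:
            logger.error("repetition %d failed: %s", r, exc)
            failures.append((r, str(exc)))
    rows = pd.DataFrame.from_records(records)
    return RepetitionReport(rows=rows, n_reps=n_reps, failures=failures)


def optima_table(
    report: RepetitionReport, grid: PipelineGrid, which: str = "sampled_optimum"
) -> pd.DataFrame:
    """Factor levels plus hold-out score of each repetition's optimum, in the
    layout of a per-repetition optima listing."""
    rows = []
    for _, rec in report.rows.iterrows():
        spec = grid[int(rec[which])]
        row = dict(spec.factors)
        row["score"] = rec["holdout_score"]
        rows.append(row)
    return pd.DataFrame(rows)


def make_synthetic_landscape(
    n_pipelines: int = 128,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[PipelineGrid, EmbeddedSpace, "SyntheticLandscapeEvaluator"]:
    """Benchmark landscape with a known optimum region.

    Pipelines get uniform coordinates in the unit square; the score surface is
    a two-bump Gaussian mixture (global optimum at (0.7, 0.3)), optionally
    with additive evaluation noise.  Returns (grid, embedded space, evaluator)
    ready for :func:`pipeverse.search.run_search`.
    """
    rng = np.random.default_rng(seed)
    coords = rng.uniform(size=(n_pipelines, 2))
    grid = build_grid({"pipeline": [f"p{i:04d}" for i in range(n_pipelines)]})
    space = EmbeddedSpace(
        coords=coords,
        method="synthetic",
        params={"seed": seed, "n_pipelines": n_pipelines},
        pipeline_ids=np.arange(n_pipelines),
    )
    evaluator = SyntheticLandscapeEvaluator(coords, noise_sd=noise_sd, seed=seed)
    return grid, space, evaluator


class SyntheticLandscapeEvaluator:
    """Deterministic smooth score surface over embedded coordinates."""

    peaks = (
        (np.array([0.7, 0.3]), 1.0, 0.12),
        (np.array([0.2, 0.8]), 0.6, 0.18),
    )

    def __init__(self, coords: np.ndarray, noise_sd: float = 0.0, seed: int = 0):
        self.coords = coords
        self.noise_sd = noise_sd
        self.seed = seed

    def surface(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        val = np.zeros(len(x))
        for center, height, width in self.peaks:
            val += height * np.exp(-np.sum((x - center) ** 2, axis=1) / (2 * width**2))
        return val

    def true_scores(self) -> np.ndarray:
        return self.surface(self.coords)

    def __call__(self, spec: PipelineSpec) -> Score:
        value = float(self.surface(self.coords[spec.id])[0])
        if self.noise_sd > 0:
            rng = np.random.default_rng((self.seed * 1_000_003 + spec.id) % 2**31)
            value += float(rng.normal(scale=self.noise_sd))
        return Score(pipeline_id=spec.id, value=value, fold_values=np.array([value]), seed=self.seed)
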
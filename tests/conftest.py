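"""Shared fixtures: small synthetic cohorts, grids and search runs.

Heavy artifacts (similarity tables, repeated searches) are session-scoped so
the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import pipeverse as pv
from pipeverse.evaluation import make_synthetic_landscape

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

#: the six nodal metrics every registry must provide
MANDATORY_METRICS = (
    "strength",
    "betweenness_centrality",
    "eigenvector_centrality",
    "gateway_degree",
    "module_degree_zscore",
    "modularity_louvain",
)


@pytest.fixture(scope="session")
def reg_cohort() -> pv.SubjectDataset:
    """Regression-style cohort: 40 subjects, 12 regions, two data variants."""
    config = pv.SyntheticCohortConfig(
        n_subjects=40, n_regions=12, n_timepoints=100, signal_strength=0.5, seed=5
    )
    dataset = pv.generate_cohort(config)
    return pv.split_dataset(dataset, sizes=(15, 20, 5), seed=1)


@pytest.fixture(scope="session")
def reg_grid() -> pv.PipelineGrid:
    return pv.default_regression_grid(
        sparsities=(0.05, 0.1, 0.2, 0.3), graph_metrics=MANDATORY_METRICS
    )


@pytest.fixture(scope="session")
def reg_cache() -> pv.PipelineCache:
    return pv.PipelineCache()


@pytest.fixture(scope="session")
def reg_table(reg_cohort, reg_grid, reg_cache) -> pv.SimilarityTable:
    return pv.build_similarity_table(reg_cohort, reg_grid, cache=reg_cache)


@pytest.fixture(scope="session")
def reg_space(reg_table) -> pv.EmbeddedSpace:
    return pv.embed(reg_table, method="mds", seed=3)


@pytest.fixture(scope="session")
def clf_grid() -> pv.PipelineGrid:
    return pv.default_classification_grid(
        preproc_variants=("ccs", "cpac"),
        strategies=("filt_global", "filt_noglobal"),
        parcellations=("rois_ho", "rois_tt"),
    )


@pytest.fixture(scope="session")
def clf_cohort(clf_grid) -> pv.SubjectDataset:
    """Classification-style cohort with multi-parcellation variants."""
    config = pv.SyntheticCohortConfig(
        n_subjects=36, n_regions=8, n_timepoints=80, task="classification", seed=4
    )
    dataset = pv.generate_multifactor_cohort(
        config,
        preproc_levels=clf_grid.factor_levels["preproc_variant"],
        strategy_levels=clf_grid.factor_levels["strategy"],
        parcellation_regions={"rois_ho": 8, "rois_tt": 10},
    )
    return pv.split_dataset(dataset, sizes=(12, 18, 6), stratify=True, seed=0)


@pytest.fixture(scope="session")
def landscape128():
    """128-pipeline synthetic landscape with known optimum plus its empirical
    (exhaustively evaluated) scores."""
    grid, space, evaluator = make_synthetic_landscape(n_pipelines=128, seed=42)
    empirical = pv.exhaustive_evaluate(
        None, grid, pv.SearchConfig(seed=0), evaluator=evaluator
    )
    return grid, space, evaluator, empirical


@pytest.fixture(scope="session")
def landscape_paired_runs(landscape128):
    """Ten paired full-budget searches (kappa 10 vs 0.1) on the landscape."""
    grid, space, evaluator, _ = landscape128
    runs = []
    for seed in range(10):
        tr10 = pv.run_search(
            None, grid, space, pv.SearchConfig(kappa=10.0, seed=seed), evaluator=evaluator
        )
        tr01 = pv.run_search(
            None, grid, space, pv.SearchConfig(kappa=0.1, seed=seed), evaluator=evaluator
        )
        runs.append((tr10, tr01))
    return runs


@pytest.fixture(scope="session")
def landscape_report(landscape128):
    """Twenty exploratory repetitions of the search on the landscape."""
    grid, space, evaluator, empirical = landscape128
    return pv.repeat_search(
        None,
        grid,
        space,
        pv.SearchConfig(kappa=10.0, n_iterations=20),
        n_reps=20,
        base_seed=100,
        evaluator=evaluator,
        empirical=empirical,
        score_holdout=False,
    )
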
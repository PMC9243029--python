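"""Grid construction, connectivity estimators, thresholding, nodal metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.linalg import logm as scipy_logm

import pipeverse as pv
from pipeverse.metrics import COMMUNITY_METRICS, NODAL_METRICS
from pipeverse.pipelines import (
    FC_METRICS,
    PipelineGrid,
    PipelineSpec,
    features_matrix,
)
from conftest import MANDATORY_METRICS

# ---------------------------------------------------------------- grids


def test_default_grid_cardinalities():
    assert len(pv.default_regression_grid()) == 2 * 17 * 16 == 544
    assert len(pv.default_classification_grid()) == 4 * 4 * 6 * 4 == 384


def test_single_factor_single_level_grid():
    grid = pv.build_grid({"metric": ["strength"]})
    assert len(grid) == 1
    assert grid[0].as_dict() == {"metric": "strength"}


def test_duplicate_levels_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        pv.build_grid({"metric": ["strength", "strength"]})
    with pytest.raises(ValueError):
        pv.build_grid({})
    with pytest.raises(ValueError):
        pv.build_grid({"metric": []})


@given(
    st.lists(st.integers(min_value=1, max_value=5), min_size=1, max_size=4)
)
def test_grid_size_is_product_of_level_counts(level_counts):
    factors = {
        f"f{i}": [f"f{i}_l{j}" for j in range(n)] for i, n in enumerate(level_counts)
    }
    grid = pv.build_grid(factors)
    assert len(grid) == math.prod(level_counts)
    assert [p.id for p in grid] == list(range(len(grid)))
    # last factor varies fastest
    if len(grid) > 1:
        last = grid.pipelines[0].factor_names[-1]
        if len(factors[last]) > 1:
            assert grid[0][last] != grid[1][last]


# ---------------------------------------------------------------- connectivity


def test_correlation_of_identical_regions_is_one():
    t = np.arange(10.0)
    ts = np.vstack([t, 2 * t + 1, -t])
    fc = pv.compute_fc(ts, "correlation")
    assert fc[0, 1] == pytest.approx(1.0)
    assert fc[0, 2] == pytest.approx(-1.0)
    assert np.allclose(np.diag(fc), 1.0)
    assert np.abs(fc).max() <= 1.0


def test_tangent_projection_at_own_reference_is_zero():
    rng = np.random.default_rng(0)
    ts = rng.standard_normal((4, 60))
    ref = np.cov(ts)
    tangent = pv.compute_fc(ts, "tangent", reference=ref)
    assert np.allclose(tangent, 0.0, atol=1e-9)


def test_tangent_matches_scipy_logm():
    rng = np.random.default_rng(1)
    ts = rng.standard_normal((4, 80))
    ref = np.cov(rng.standard_normal((4, 80))) + 0.5 * np.eye(4)
    ours = pv.compute_fc(ts, "tangent", reference=ref)
    vals, vecs = np.linalg.eigh(ref)
    w = (vecs * vals**-0.5) @ vecs.T
    expected = scipy_logm(w @ np.cov(ts) @ w)
    assert np.allclose(ours, np.real(expected), atol=1e-8)


def test_partial_correlation_matches_residual_oracle():
    """Pairwise partial correlation equals the correlation of regression
    residuals after removing the remaining region."""
    rng = np.random.default_rng(7)
    ts = rng.standard_normal((3, 50))
    ours = pv.compute_fc(ts, "partial_correlation")
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        (k,) = set(range(3)) - {i, j}
        z = np.vstack([np.ones(50), ts[k]]).T
        ri = ts[i] - z @ np.linalg.lstsq(z, ts[i], rcond=None)[0]
        rj = ts[j] - z @ np.linalg.lstsq(z, ts[j], rcond=None)[0]
        expected = np.corrcoef(ri, rj)[0, 1]
        assert ours[i, j] == pytest.approx(expected, abs=1e-8)


def test_compute_fc_input_validation():
    with pytest.raises(ValueError):
        pv.compute_fc(np.zeros((3, 2)), "correlation")
    with pytest.raises(ValueError):
        pv.compute_fc(np.zeros((3, 10)), "tangent")  # no reference
    with pytest.raises(ValueError):
        pv.compute_fc(np.zeros((3, 10)), "mutual_information")


def test_tangent_reference_trivial_cases():
    a = np.array([[2.0, 0.3], [0.3, 1.0]])
    assert np.allclose(pv.tangent_reference([a]), a)
    assert np.allclose(pv.tangent_reference([a, a]), a)
    d1, d3 = np.diag([1.0, 1.0]), np.diag([3.0, 3.0])
    assert np.allclose(pv.tangent_reference([d1, d3]), np.diag([2.0, 2.0]))
    with pytest.raises(ValueError):
        pv.tangent_reference([d1, np.eye(3)])


def test_geometric_reference_is_geometric_mean_for_diagonals():
    ref = pv.tangent_reference([np.diag([1.0, 4.0]), np.diag([4.0, 1.0])], method="geometric")
    assert np.allclose(ref, np.diag([2.0, 2.0]), atol=1e-8)


def test_tangent_projections_around_mean_sum_near_zero():
    """For commuting (diagonal) covariances near their Euclidean mean, tangent
    vectors at the mean reference sum approximately to zero; at the geometric
    mean they sum to zero exactly."""
    rng = np.random.default_rng(3)
    covs = [np.diag(1.0 + 0.1 * rng.uniform(-1, 1, size=3)) for _ in range(6)]

    def tangent_sum(ref):
        vals, vecs = np.linalg.eigh(ref)
        w = (vecs * vals**-0.5) @ vecs.T
        logs = []
        for c in covs:
            m = w @ c @ w
            lv, le = np.linalg.eigh(m)
            logs.append((le * np.log(lv)) @ le.T)
        return np.mean(logs, axis=0)

    assert np.abs(tangent_sum(pv.tangent_reference(covs))).max() < 0.01
    assert np.abs(tangent_sum(pv.tangent_reference(covs, method="geometric"))).max() < 1e-8


# ---------------------------------------------------------------- thresholding


def test_threshold_s1_keeps_everything_off_diagonal():
    rng = np.random.default_rng(2)
    m = rng.standard_normal((5, 5))
    m = m + m.T
    out = pv.proportional_threshold(m, 1.0)
    off = ~np.eye(5, dtype=bool)
    assert np.array_equal(out[off], m[off])
    assert np.all(np.diag(out) == 0)


def test_threshold_keeps_three_strongest_of_six():
    m = np.zeros((4, 4))
    weights = iter([6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
    for i in range(4):
        for j in range(i + 1, 4):
            m[i, j] = m[j, i] = next(weights)
    out = pv.proportional_threshold(m, 0.5)
    kept = sorted((v for v in out[np.triu_indices(4, k=1)] if v != 0), reverse=True)
    assert kept == [6.0, 5.0, 4.0]


def test_threshold_tie_break_is_lexicographic():
    m = np.zeros((4, 4))
    # pairs (0,1)=(0,2)=2.0 tie; (0,3)=3.0; rest 1.0
    m[0, 1] = m[1, 0] = 2.0
    m[0, 2] = m[2, 0] = 2.0
    m[0, 3] = m[3, 0] = 3.0
    m[1, 2] = m[2, 1] = 1.0
    m[1, 3] = m[3, 1] = 1.0
    m[2, 3] = m[3, 2] = 1.0
    out = pv.proportional_threshold(m, 2 / 6)  # keep 2 of 6
    assert out[0, 3] == 3.0
    assert out[0, 1] == 2.0  # (0,1) precedes (0,2) lexicographically
    assert out[0, 2] == 0.0


@given(st.integers(min_value=2, max_value=8), st.floats(min_value=0.01, max_value=1.0))
def test_threshold_edge_count_is_ceil_s_e(n, s):
    rng = np.random.default_rng(n)
    vals = rng.permutation(n * (n - 1) // 2) + 1.0  # unique, tie-free
    m = np.zeros((n, n))
    m[np.triu_indices(n, k=1)] = vals
    m = m + m.T
    out = pv.proportional_threshold(m, s)
    kept = np.count_nonzero(out[np.triu_indices(n, k=1)])
    assert kept == math.ceil(s * (n * (n - 1) // 2))


def test_threshold_zero_matrix_warns():
    with pytest.warns(UserWarning, match="all-zero"):
        out = pv.proportional_threshold(np.zeros((3, 3)), 0.5)
    assert np.array_equal(out, np.zeros((3, 3)))
    with pytest.raises(ValueError):
        pv.proportional_threshold(np.zeros((3, 3)), 0.0)


# ---------------------------------------------------------------- nodal metrics


def test_strength_on_unit_line():
    m = np.zeros((3, 3))
    m[0, 1] = m[1, 0] = 1.0
    m[1, 2] = m[2, 1] = 1.0
    assert np.allclose(pv.nodal_metric(m, "strength"), [1.0, 2.0, 1.0])


def test_betweenness_on_path_graph():
    m = np.zeros((3, 3))
    m[0, 1] = m[1, 0] = 1.0
    m[1, 2] = m[2, 1] = 1.0
    b = pv.nodal_metric(m, "betweenness_centrality")
    assert b[1] > b[0] and b[1] > b[2]
    assert b[0] == 0.0 and b[2] == 0.0


def test_eigenvector_star_matches_power_iteration():
    m = np.zeros((4, 4))
    for leaf in (1, 2, 3):
        m[0, leaf] = m[leaf, 0] = 1.0
    ours = pv.nodal_metric(m, "eigenvector_centrality")
    # power iteration on A + I (same eigenvectors, breaks the bipartite
    # +/-sqrt(3) eigenvalue tie so the iteration converges)
    shifted = m + np.eye(4)
    v = np.ones(4) / 2.0
    for _ in range(200):
        v = shifted @ v
        v = v / np.linalg.norm(v)
    assert ours[0] > ours[1:].max()
    assert np.allclose(ours, np.abs(v), atol=1e-6)


def test_registry_is_complete_and_guarded():
    assert len(NODAL_METRICS) == 16
    assert set(MANDATORY_METRICS) <= set(NODAL_METRICS)
    with pytest.raises(ValueError, match="registry"):
        pv.nodal_metric(np.eye(3), "hubness")
    for name in COMMUNITY_METRICS:
        with pytest.raises(ValueError, match="community"):
            pv.nodal_metric(np.ones((3, 3)), name, communities=None)


@pytest.mark.parametrize("metric", sorted(NODAL_METRICS))
def test_every_metric_finite_on_thresholded_fc(metric):
    rng = np.random.default_rng(0)
    ts = rng.standard_normal((10, 60))
    w = pv.proportional_threshold(pv.compute_fc(ts, "correlation"), 0.3)
    communities = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 2])
    values = pv.nodal_metric(w, metric, communities=communities, seed=1)
    assert values.shape == (10,)
    assert np.all(np.isfinite(values))


# ---------------------------------------------------------------- execution


def test_apply_pipeline_equals_manual_composition(reg_cohort, reg_grid):
    spec = next(
        p
        for p in reg_grid
        if p["data_variant"] == "motion_regression"
        and p["sparsity"] == 0.1
        and p["graph_metric"] == "strength"
    )
    subjects = reg_cohort.split_indices("space")[:3]
    feats = pv.apply_pipeline(reg_cohort, spec, subjects=subjects, seed=0)
    from pipeverse.pipelines import _metric_seed

    for row, i in zip(feats, subjects):
        fc = pv.compute_fc(reg_cohort.variants["motion_regression"][i], "correlation")
        expected = pv.nodal_metric(
            pv.proportional_threshold(fc, 0.1),
            "strength",
            communities=reg_cohort.communities["motion_regression"],
            seed=_metric_seed(0, spec.id),
        )
        assert np.allclose(row.values, expected)
        assert row.values.shape == (12,)


def test_identical_subjects_identical_features(reg_cohort, reg_grid):
    spec = reg_grid[5]
    a = pv.apply_pipeline(reg_cohort, spec, subjects=[3, 3])
    assert np.array_equal(a[0].values, a[1].values)


def test_classification_vectorization_length():
    config = pv.SyntheticCohortConfig(
        n_subjects=6, n_regions=30, n_timepoints=40, task="classification", seed=0
    )
    ds = pv.generate_multifactor_cohort(config, ["p"], ["filt_global"], {"parc": 30})
    grid = pv.default_classification_grid(
        preproc_variants=("p",), strategies=("filt_global",), parcellations=("parc",)
    )
    spec = next(p for p in grid if p["fc_metric"] == "correlation")
    feats = pv.apply_pipeline(ds, spec)
    assert features_matrix(feats).shape == (6, 30 * 29 // 2)


@pytest.mark.parametrize("fc_metric", FC_METRICS)
def test_classification_estimators_run(clf_cohort, clf_grid, fc_metric):
    spec = next(p for p in clf_grid if p["fc_metric"] == fc_metric)
    feats = pv.apply_pipeline(clf_cohort, spec, subjects=clf_cohort.split_indices("space"))
    X = features_matrix(feats)
    assert X.shape == (12, 8 * 7 // 2)
    assert np.all(np.isfinite(X))


def test_missing_variant_errors(reg_cohort):
    grid = pv.default_regression_grid(data_variants=("scrubbing",), sparsities=(0.1,))
    with pytest.raises(KeyError, match="scrubbing"):
        pv.apply_pipeline(reg_cohort, grid[0])
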
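"""Multiverse pipeline grids and their execution.

A *pipeline* is one full combination of analysis choices.  Two study designs
are supported:

- regression design: data variant (motion vs global-signal regression) x
  proportional-threshold sparsity x nodal graph metric; each subject yields a
  feature vector of one nodal value per region;
- classification design: preprocessing suite x processing strategy x
  parcellation x connectivity estimator (covariance, correlation, partial
  correlation, tangent); each subject yields the strict lower triangle of the
  connectivity matrix.

The Cartesian product of the factor levels forms the pipeline grid; pipeline
ids enumerate it in product order with the last factor varying fastest.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .metrics import COMMUNITY_METRICS, NODAL_METRICS, as_graph
from .synthetic_data import SubjectDataset

logger = logging.getLogger(__name__)

FC_METRICS = ("covariance", "correlation", "partial_correlation", "tangent")

#: 17 proportional-threshold sparsities spanning 0.01 (very sparse) to 0.4
#: (dense); includes every value at which optima are commonly reported.
DEFAULT_SPARSITIES = (
    0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.08, 0.10, 0.125, 0.15,
    0.175, 0.20, 0.225, 0.25, 0.275, 0.30, 0.40,
)

DEFAULT_DATA_VARIANTS = ("motion_regression", "global_signal_regression")
DEFAULT_PREPROC_VARIANTS = ("ccs", "cpac", "dparsf", "niak")
DEFAULT_STRATEGIES = ("filt_global", "filt_noglobal", "nofilt_global", "nofilt_noglobal")
DEFAULT_PARCELLATIONS = (
    "rois_dosenbach160", "rois_cc200", "rois_cc400", "rois_ez", "rois_ho", "rois_tt",
)


@dataclass(frozen=True)
class PipelineSpec:
    """One point of the multiverse: an ordered factor -> level mapping plus a
    stable integer id in grid order."""

    factors: tuple[tuple[str, object], ...]
    id: int

    def __getitem__(self, name: str):
        for key, level in self.factors:
            if key == name:
                return level
        raise KeyError(name)

    def as_dict(self) -> dict:
        return dict(self.factors)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.factors)


@dataclass
class PipelineGrid:
    """Cartesian product of factor levels, last factor fastest."""

    factor_levels: dict[str, tuple]
    pipelines: list[PipelineSpec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pipelines)

    def __getitem__(self, pipeline_id: int) -> PipelineSpec:
        return self.pipelines[pipeline_id]

    def __iter__(self):
        return iter(self.pipelines)


@dataclass
class FeatureVector:
    """Per-subject feature vector produced by one pipeline."""

    subject_id: str
    values: np.ndarray
    pipeline_id: int


def build_grid(factor_levels: Mapping[str, Sequence]) -> PipelineGrid:
    """Expand factor levels into the full pipeline grid.

    Raises on an empty declaration or duplicate levels within a factor.
    """
    if not factor_levels:
        raise ValueError("at least one factor is required")
    levels: dict[str, tuple] = {}
    for name, lv in factor_levels.items():
        lv = tuple(lv)
        if not lv:
            raise ValueError(f"factor {name!r} has no levels")
        if len(set(lv)) != len(lv):
            raise ValueError(f"factor {name!r} has duplicate levels: {lv}")
        levels[name] = lv
    names = tuple(levels)
    specs = [
        PipelineSpec(factors=tuple(zip(names, combo)), id=i)
        for i, combo in enumerate(itertools.product(*levels.values()))
    ]
    return PipelineGrid(factor_levels=levels, pipelines=specs)


def default_regression_grid(
    data_variants: Sequence[str] = DEFAULT_DATA_VARIANTS,
    sparsities: Sequence[float] = DEFAULT_SPARSITIES,
    graph_metrics: Sequence[str] | None = None,
) -> PipelineGrid:
    """2 x 17 x 16 = 544 pipelines by default."""
    metrics = tuple(graph_metrics) if graph_metrics is not None else tuple(NODAL_METRICS)
    return build_grid(
        {"data_variant": data_variants, "sparsity": sparsities, "graph_metric": metrics}
    )


def default_classification_grid(
    preproc_variants: Sequence[str] = DEFAULT_PREPROC_VARIANTS,
    strategies: Sequence[str] = DEFAULT_STRATEGIES,
    parcellations: Sequence[str] = DEFAULT_PARCELLATIONS,
    fc_metrics: Sequence[str] = FC_METRICS,
) -> PipelineGrid:
    """4 x 4 x 6 x 4 = 384 pipelines by default."""
    return build_grid(
        {
            "preproc_variant": preproc_variants,
            "strategy": strategies,
            "parcellation": parcellations,
            "fc_metric": fc_metrics,
        }
    )


def _ridge_if_needed(cov: np.ndarray, max_cond: float = 1e12) -> np.ndarray:
    eigs = np.linalg.eigvalsh(cov)
    if eigs[0] <= 0 or eigs[-1] / max(eigs[0], 1e-300) > max_cond:
        lam = 1e-6 * float(np.mean(np.diag(cov)))
        logger.debug("ill-conditioned covariance; ridge-regularizing with %.3e", lam)
        return cov + lam * np.eye(cov.shape[0])
    return cov


def _sym_logm(spd: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(spd)
    return (vecs * np.log(np.clip(vals, 1e-12, None))) @ vecs.T


def _sym_powm(spd: np.ndarray, power: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(spd)
    return (vecs * np.clip(vals, 1e-12, None) ** power) @ vecs.T


def compute_fc(
    timeseries: np.ndarray, metric: str, reference: np.ndarray | None = None
) -> np.ndarray:
    """Region x region connectivity from a region x time matrix.

    ``covariance`` and ``correlation`` are the sample estimators;
    ``partial_correlation`` is -Omega_ij / sqrt(Omega_ii Omega_jj) from the
    (ridge-regularized when ill-conditioned) precision Omega; ``tangent``
    projects the covariance into the tangent space at ``reference``:
    logm(ref^{-1/2} C ref^{-1/2}).
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ValueError("timeseries must be a region x time matrix with >= 3 timepoints")
    if metric == "covariance":
        return np.cov(ts)
    if metric == "correlation":
        c = np.corrcoef(ts)
        c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(c, 1.0)
        return c
    if metric == "partial_correlation":
        cov = _ridge_if_needed(np.cov(ts))
        prec = np.linalg.inv(cov)
        d = np.sqrt(np.diag(prec))
        p = -prec / np.outer(d, d)
        np.fill_diagonal(p, 1.0)
        return (p + p.T) / 2.0
    if metric == "tangent":
        if reference is None:
            raise ValueError("tangent projection requires a reference covariance")
        cov = _ridge_if_needed(np.cov(ts))
        whitener = _sym_powm(np.asarray(reference, dtype=float), -0.5)
        m = whitener @ cov @ whitener
        return _sym_logm((m + m.T) / 2.0)
    raise ValueError(f"unknown connectivity metric {metric!r}; expected one of {FC_METRICS}")


def tangent_reference(
    covariances: Sequence[np.ndarray], method: str = "euclidean"
) -> np.ndarray:
    """Reference point for tangent projection.

    ``euclidean`` (default): element-wise mean projected back to positive
    definite by flooring eigenvalues at 1e-10.  ``geometric``: Karcher mean
    under the affine-invariant metric, by fixed-point iteration.
    """
    covs = [np.asarray(c, dtype=float) for c in covariances]
    if not covs:
        raise ValueError("at least one covariance matrix is required")
    shape = covs[0].shape
    if any(c.shape != shape for c in covs):
        raise ValueError("all covariance matrices must have the same size")
    mean = np.mean(covs, axis=0)
    mean = (mean + mean.T) / 2.0
    vals, vecs = np.linalg.eigh(mean)
    ref = (vecs * np.clip(vals, 1e-10, None)) @ vecs.T
    if method == "euclidean":
        return ref
    if method == "geometric":
        for _ in range(50):
            w = _sym_powm(ref, -0.5)
            wi = _sym_powm(ref, 0.5)
            log_mean = np.mean([_sym_logm(w @ c @ w) for c in covs], axis=0)
            step_vals, step_vecs = np.linalg.eigh((log_mean + log_mean.T) / 2.0)
            step = (step_vecs * np.exp(step_vals)) @ step_vecs.T
            ref = wi @ step @ wi
            ref = (ref + ref.T) / 2.0
            if np.linalg.norm(log_mean) < 1e-10:
                break
        return ref
    raise ValueError(f"unknown tangent reference method {method!r}")


def proportional_threshold(fc: np.ndarray, s: float) -> np.ndarray:
    """Keep the ``ceil(s * E)`` strongest of the E = n(n-1)/2 unique edges.

    Retained weights are preserved (no binarization); the diagonal is zeroed.
    Ties at the cut are broken by lexicographic (i, j) pair order.
    """
    if not (0.0 < s <= 1.0):
        raise ValueError(f"sparsity must lie in (0, 1], got {s}")
    fc = np.asarray(fc, dtype=float)
    n = fc.shape[0]
    i, j = np.triu_indices(n, k=1)
    w = fc[i, j]
    out = np.zeros_like(fc)
    if not np.any(w != 0):
        warnings.warn("proportional_threshold: all-zero matrix returned unchanged")
        return out
    k = math.ceil(s * len(w))
    order = np.lexsort((j, i, -w))
    keep = order[:k]
    out[i[keep], j[keep]] = w[keep]
    out[j[keep], i[keep]] = w[keep]
    return out


def nodal_metric(
    adjacency: np.ndarray,
    metric: str,
    communities: np.ndarray | None = None,
    seed: int = 0,
    graph=None,
) -> np.ndarray:
    """Evaluate one registered nodal metric on a weighted adjacency matrix."""
    if metric not in NODAL_METRICS:
        raise ValueError(
            f"unknown nodal metric {metric!r}; registry: {sorted(NODAL_METRICS)}"
        )
    if metric in COMMUNITY_METRICS and communities is None:
        raise ValueError(f"metric {metric!r} requires a community assignment")
    values = NODAL_METRICS[metric](
        adjacency, communities=communities, seed=seed, graph=graph
    )
    return np.asarray(values, dtype=float)


class PipelineCache:
    """Memoization shared across pipelines operating on one dataset.

    Caches per-subject connectivity, thresholded adjacencies and their graph
    views, and tangent references, so that sweeping a full grid does not
    recompute shared intermediates.
    """

    def __init__(self) -> None:
        self._store: dict = {}

    def get_or(self, key, fn: Callable):
        if key not in self._store:
            self._store[key] = fn()
        return self._store[key]


def _is_regression_design(spec: PipelineSpec) -> bool:
    names = spec.factor_names
    if "graph_metric" in names:
        return True
    if "fc_metric" in names:
        return False
    raise ValueError(
        f"cannot infer design from factors {names}; expected 'graph_metric' or 'fc_metric'"
    )


def classification_variant_label(spec: PipelineSpec) -> str:
    return "|".join(
        (str(spec["preproc_variant"]), str(spec["strategy"]), str(spec["parcellation"]))
    )


def _metric_seed(seed: int, pipeline_id: int) -> int:
    return (seed * 1_000_003 + 7919 * pipeline_id) % 2**31


def apply_pipeline(
    dataset: SubjectDataset,
    spec: PipelineSpec,
    subjects: Sequence[int] | None = None,
    cache: PipelineCache | None = None,
    seed: int = 0,
) -> list[FeatureVector]:
    """Run one pipeline end-to-end on (a subset of) the cohort.

    Regression design: Pearson-correlation connectivity on the spec's data
    variant -> proportional threshold -> nodal metric, one value per region.
    Classification design: connectivity by the spec's estimator on the data
    variant selected by its preprocessing factors -> strict lower triangle.
    """
    cache = cache if cache is not None else PipelineCache()
    idx = np.arange(dataset.n_subjects) if subjects is None else np.asarray(subjects)
    if _is_regression_design(spec):
        return _apply_regression(dataset, spec, idx, cache, seed)
    return _apply_classification(dataset, spec, idx, cache, seed)


def _variant_data(dataset: SubjectDataset, label: str) -> np.ndarray:
    if label not in dataset.variants:
        raise KeyError(
            f"data variant {label!r} missing from dataset (has {sorted(dataset.variants)})"
        )
    return dataset.variants[label]


def _apply_regression(dataset, spec, idx, cache, seed) -> list[FeatureVector]:
    variant = str(spec["data_variant"])
    s = float(spec["sparsity"])
    metric = str(spec["graph_metric"])
    data = _variant_data(dataset, variant)
    communities = dataset.communities.get(variant)
    mseed = _metric_seed(seed, spec.id)
    out = []
    for i in idx:
        i = int(i)
        if dataset.data_kind == "connectivity":
            fc = cache.get_or(("fc", variant, i), lambda: np.asarray(data[i], dtype=float))
        else:
            fc = cache.get_or(("fc", variant, i), lambda: compute_fc(data[i], "correlation"))
        thr = cache.get_or(("thr", variant, i, s), lambda: proportional_threshold(fc, s))
        graph = cache.get_or(("graph", variant, i, s), lambda: as_graph(thr))
        values = nodal_metric(thr, metric, communities=communities, seed=mseed, graph=graph)
        if not np.all(np.isfinite(values)):
            raise FloatingPointError(
                f"non-finite features from metric {metric!r} (pipeline {spec.id})"
            )
        out.append(FeatureVector(dataset.subject_ids[i], values, spec.id))
    return out


def _apply_classification(dataset, spec, idx, cache, seed) -> list[FeatureVector]:
    variant = classification_variant_label(spec)
    fc_metric = str(spec["fc_metric"])
    data = _variant_data(dataset, variant)
    n_regions = data.shape[1]
    il = np.tril_indices(n_regions, k=-1)

    def cov_of(i: int) -> np.ndarray:
        return cache.get_or(("cov", variant, int(i)), lambda: np.cov(np.asarray(data[i], float)))

    reference = None
    if fc_metric == "tangent":
        subj_key = tuple(int(i) for i in idx)
        reference = cache.get_or(
            ("tref", variant, subj_key),
            lambda: tangent_reference([cov_of(i) for i in idx]),
        )
    out = []
    for i in idx:
        i = int(i)
        if fc_metric == "covariance":
            fc = cov_of(i)
        else:
            fc = cache.get_or(
                ("fc", variant, fc_metric, i, id(reference) if reference is not None else 0),
                lambda: compute_fc(data[i], fc_metric, reference=reference),
            )
        values = fc[il]
        if not np.all(np.isfinite(values)):
            raise FloatingPointError(
                f"non-finite connectivity features (pipeline {spec.id})"
            )
        out.append(FeatureVector(dataset.subject_ids[i], values, spec.id))
    return out


def features_matrix(features: Sequence[FeatureVector]) -> np.ndarray:
    """Stack per-subject feature vectors into a subjects x features matrix."""
    return np.vstack([f.values for f in features])
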
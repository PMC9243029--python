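"""Low-dimensional embedding of the pipeline multiverse.

Each pipeline is summarized by its *between-participant similarity signature*:
the cosine similarity between every unordered pair of subjects' feature
vectors, giving a pipelines x pairs table.  Pipelines whose signatures are
close produce similar individual-differences structure, so embedding the
table's rows (metric MDS by default, PCA as the linear alternative) yields a
space in which proximal pipelines behave alike — the substrate for
surrogate-model search.

Embedding quality is scored by neighborhood preservation: the mean fraction of
each pipeline's k nearest neighbors in the original dissimilarity that remain
among its k nearest neighbors after embedding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .pipelines import PipelineCache, PipelineGrid, apply_pipeline, features_matrix
from .synthetic_data import SubjectDataset

logger = logging.getLogger(__name__)


@dataclass
class SimilarityTable:
    """Pipelines (rows) x participant pairs (columns) of cosine similarities.

    The transposed orientation (pairs x pipelines) is an equally common way to
    print the same table; rows-as-pipelines is used throughout because the
    embedding treats pipelines as the observations.
    """

    matrix: np.ndarray
    pair_index: list[tuple[int, int]]
    pipeline_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.pair_index):
            raise ValueError("column count must equal the number of subject pairs")


@dataclass
class EmbeddedSpace:
    """Per-pipeline coordinates in the embedded space."""

    coords: np.ndarray
    method: str
    params: dict
    pipeline_ids: np.ndarray
    stress: float | None = None


def pair_count(n_subjects: int) -> int:
    """Number of unordered subject pairs, n(n-1)/2 (self-pairs excluded)."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return n_subjects * (n_subjects - 1) // 2


def pair_index(n_subjects: int) -> list[tuple[int, int]]:
    """Unordered pairs (i, j), i < j, in row-major order."""
    return [(i, j) for i in range(n_subjects) for j in range(i + 1, n_subjects)]


def subject_similarity(features: np.ndarray | Sequence) -> np.ndarray:
    """Cosine similarity for every unordered subject pair, in pair-index order.

    A zero-norm feature vector gets similarity 0 with every other subject
    (logged), rather than propagating NaN.
    """
    X = features if isinstance(features, np.ndarray) else features_matrix(features)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("at least two equal-length subject feature vectors are required")
    if not np.all(np.isfinite(X)):
        raise ValueError("subject features must be finite")
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if zero.any():
        logger.info("%d zero-norm feature vectors; their similarities are set to 0", zero.sum())
    safe = np.where(zero, 1.0, norms)
    U = X / safe[:, None]
    U[zero] = 0.0
    sim = np.clip(U @ U.T, -1.0, 1.0)
    iu = np.triu_indices(X.shape[0], k=1)
    return sim[iu]


def build_similarity_table(
    dataset: SubjectDataset,
    grid: PipelineGrid,
    subjects: Sequence[int] | None = None,
    cache: PipelineCache | None = None,
    seed: int = 0,
) -> SimilarityTable:
    """Apply every pipeline to the space-split subjects and collect each
    pipeline's between-participant similarity signature."""
    if subjects is None:
        subjects = dataset.split_indices("space")
    subjects = np.asarray(subjects)
    if len(subjects) < 2:
        raise ValueError("the space split must contain at least two subjects")
    cache = cache if cache is not None else PipelineCache()
    rows = np.empty((len(grid), pair_count(len(subjects))))
    for spec in grid:
        try:
            feats = apply_pipeline(dataset, spec, subjects=subjects, cache=cache, seed=seed)
            rows[spec.id] = subject_similarity(features_matrix(feats))
        except Exception as exc:
            raise RuntimeError(f"pipeline {spec.id} ({spec.as_dict()}) failed") from exc
    return SimilarityTable(
        matrix=rows,
        pair_index=pair_index(len(subjects)),
        pipeline_ids=np.arange(len(grid)),
    )


def _row_dissimilarity(table: SimilarityTable, kind: str) -> np.ndarray:
    if kind == "euclidean":
        return squareform(pdist(table.matrix, metric="euclidean"))
    if kind == "correlation":
        return squareform(pdist(table.matrix, metric="correlation"))
    raise ValueError(f"unknown dissimilarity {kind!r}; expected 'euclidean' or 'correlation'")


def _embed_mds(D: np.ndarray, d: int, seed: int) -> tuple[np.ndarray, float]:
    import inspect

    params = dict(
        n_components=d,
        random_state=seed,
        max_iter=1000,
        eps=1e-9,
        normalized_stress=False,
    )
    sig = inspect.signature(MDS.__init__).parameters
    # sklearn renamed dissimilarity='precomputed' to metric='precomputed';
    # classical (Torgerson) initialization makes SMACOF deterministic and
    # recovers exactly embeddable configurations to high precision
    if "metric_mds" in sig:
        params.update(metric="precomputed", metric_mds=True, init="classical_mds", n_init=1)
    else:  # pragma: no cover - older sklearn
        params.update(dissimilarity="precomputed", metric=True, n_init=4)
    model = MDS(**params)
    coords = model.fit_transform(D)
    return coords, float(model.stress_)


def _embed_pca(table_matrix: np.ndarray, d: int) -> np.ndarray:
    X = table_matrix - table_matrix.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    coords = U[:, :d] * s[:d]
    # deterministic sign: largest-magnitude loading of each component positive
    for c in range(coords.shape[1]):
        pivot = np.argmax(np.abs(Vt[c]))
        if Vt[c, pivot] < 0:
            coords[:, c] *= -1
    return coords


#: pluggable registry: method label -> fn(table, d, seed, dissimilarity) -> (coords, stress)
EMBEDDINGS: dict[str, Callable] = {}


def register_embedding(name: str, fn: Callable) -> None:
    """Register an additional embedding backend (e.g. t-SNE, UMAP)."""
    EMBEDDINGS[name] = fn


def embed(
    table: SimilarityTable,
    method: str = "mds",
    d: int = 2,
    seed: int = 0,
    dissimilarity: str = "euclidean",
) -> EmbeddedSpace:
    """Embed the similarity table's rows into a d-dimensional space.

    ``mds`` minimizes metric stress on pipeline-pair dissimilarities
    (Euclidean between table rows by default); ``pca`` takes the top-d
    principal coordinates of the row-centered table.  Both are deterministic
    given the seed.
    """
    if d < 2:
        raise ValueError("embedding dimension must be >= 2")
    params = {"d": d, "seed": seed, "dissimilarity": dissimilarity}
    if method == "mds":
        coords, stress = _embed_mds(_row_dissimilarity(table, dissimilarity), d, seed)
    elif method == "pca":
        coords, stress = _embed_pca(table.matrix, d), None
    elif method in EMBEDDINGS:
        coords, stress = EMBEDDINGS[method](table, d, seed, dissimilarity)
    else:
        known = ["mds", "pca", *sorted(EMBEDDINGS)]
        raise ValueError(f"unknown embedding method {method!r}; registry: {known}")
    if not np.all(np.isfinite(coords)):
        raise FloatingPointError("embedding produced non-finite coordinates")
    return EmbeddedSpace(
        coords=np.asarray(coords, dtype=float),
        method=method,
        params=params,
        pipeline_ids=table.pipeline_ids.copy(),
        stress=stress,
    )


def _knn_sets(D: np.ndarray, k: int) -> list[set]:
    """k nearest neighbors per point, self excluded, ties broken by index."""
    n = D.shape[0]
    out = []
    for i in range(n):
        order = np.lexsort((np.arange(n), D[i]))
        order = order[order != i]
        out.append(set(order[:k].tolist()))
    return out


def neighborhood_preservation(
    table: SimilarityTable,
    space: EmbeddedSpace,
    k: int,
    dissimilarity: str = "euclidean",
) -> float:
    """Mean overlap fraction between each pipeline's k nearest neighbors in
    the original dissimilarity and in the embedded Euclidean space.  1 means
    the embedding preserves every neighborhood; the complementary
    dissimilarity score is 1 minus this value."""
    P = table.matrix.shape[0]
    if not (1 <= k <= P - 1):
        raise ValueError(f"k must lie in [1, {P - 1}], got {k}")
    D_orig = _row_dissimilarity(table, dissimilarity)
    D_emb = squareform(pdist(space.coords, metric="euclidean"))
    orig = _knn_sets(D_orig, k)
    emb = _knn_sets(D_emb, k)
    return float(np.mean([len(a & b) / k for a, b in zip(orig, emb)]))
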
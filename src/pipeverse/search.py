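"""Closed-loop Bayesian optimization over the embedded pipeline space.

Each candidate pipeline is scored by cross-validated prediction on the search
split (support vector regression scored by negative mean absolute error, or
logistic regression scored by AUC).  A Gaussian process with a Matern plus
white-noise kernel is fitted to (embedded coordinates, score) pairs; the next
pipeline is chosen by maximizing the upper confidence bound mu + kappa * sigma
over the embedding's bounding box and snapping to the nearest not-yet-sampled
pipeline.  kappa tunes the exploration/exploitation trade-off: high kappa maps
the whole landscape, low kappa races to an optimum.

Scores are z-scored before GP fitting (and un-scaled on prediction) for
hyperparameter-optimization stability.  Cross-validation folds are seeded from
(global seed, pipeline id) so a pipeline's score does not depend on when the
search happens to visit it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, Matern, WhiteKernel
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import mean_absolute_error, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .pipelines import PipelineCache, PipelineGrid, PipelineSpec, apply_pipeline, features_matrix
from .space import EmbeddedSpace
from .synthetic_data import SubjectDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchConfig:
    """Search-loop configuration.

    kappa defaults to the exploratory regime (10); 0.1 gives the exploitative
    regime.  The burn-in randomly samples 10 pipelines before the acquisition
    loop starts.
    """

    kappa: float = 10.0
    n_burn_in: int = 10
    n_iterations: int = 50
    cv_folds: int = 5
    objective: str = "neg_mae"
    estimator: str = "svr"
    seed: int = 0
    kernel: str = "matern"
    kernel_nu: float = 2.5
    white_noise: bool = True
    n_acq_starts: int = 16

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_iterations < 1 or self.n_burn_in < 1:
            raise ValueError("n_burn_in and n_iterations must be >= 1")
        if self.objective not in ("neg_mae", "auc"):
            raise ValueError("objective must be 'neg_mae' or 'auc'")
        if self.estimator not in ("svr", "logistic"):
            raise ValueError("estimator must be 'svr' or 'logistic'")
        if self.kernel not in ("matern", "rbf"):
            raise ValueError("kernel must be 'matern' or 'rbf'")


@dataclass
class Score:
    """Cross-validated score of one pipeline (neg MAE in target units or AUC)."""

    pipeline_id: int
    value: float
    fold_values: np.ndarray
    seed: int
    flagged: bool = False


@dataclass
class GPModelState:
    """Fitted GP surrogate with its score-standardization parameters."""

    gpr: GaussianProcessRegressor
    train_coords: np.ndarray
    train_scores: np.ndarray
    score_mean: float
    score_sd: float
    bounds: np.ndarray  # (2, d): row 0 lower, row 1 upper

    def mu_sigma(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and sd on the raw score scale."""
        coords = np.atleast_2d(coords)
        mu_z, sd_z = self.gpr.predict(coords, return_std=True)
        return self.score_mean + self.score_sd * mu_z, self.score_sd * sd_z

    @property
    def noise_level(self) -> float:
        """Fitted white-noise sd on the raw score scale (0 without white kernel)."""
        params = self.gpr.kernel_.get_params()
        for value in params.values():
            if isinstance(value, WhiteKernel):
                return float(np.sqrt(value.noise_level)) * self.score_sd
        return 0.0


@dataclass
class TraceEntry:
    iteration: int
    pipeline_id: int
    coords: np.ndarray
    score: Score
    acquisition: float
    phase: str  # "burn_in" | "active"


@dataclass
class SearchTrace:
    entries: list[TraceEntry] = field(default_factory=list)
    gp: GPModelState | None = None
    config: SearchConfig | None = None

    @property
    def pipeline_ids(self) -> np.ndarray:
        return np.array([e.pipeline_id for e in self.entries], dtype=int)

    @property
    def scores(self) -> np.ndarray:
        return np.array([e.score.value for e in self.entries], dtype=float)


@dataclass
class LandscapeEstimate:
    """GP posterior mean and sd at every pipeline coordinate."""

    mu: np.ndarray
    sigma: np.ndarray
    pipeline_ids: np.ndarray


def fold_seed(seed: int, pipeline_id: int) -> int:
    """Deterministic CV seed per (global seed, pipeline): identical whether a
    pipeline is scored inside a search trace or by exhaustive evaluation."""
    return (seed * 1_000_003 + 7919 * pipeline_id + 12345) % 2**31


def _make_estimator(config: SearchConfig):
    if config.estimator == "svr":
        return make_pipeline(StandardScaler(), SVR(kernel="rbf", C=1.0, epsilon=0.1))
    return make_pipeline(StandardScaler(), LogisticRegression(C=1.0, max_iter=2000))


def score_features(
    X: np.ndarray, y: np.ndarray, config: SearchConfig, cv_seed: int
) -> tuple[float, np.ndarray]:
    """Cross-validated score of a feature matrix: mean held-out neg-MAE or AUC."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    folds = []
    for attempt in range(10):
        rs = (cv_seed + attempt) % 2**31
        if config.objective == "auc":
            splitter = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=rs)
            candidate = list(splitter.split(X, y))
            if all(len(np.unique(y[tr])) == 2 for tr, _ in candidate):
                folds = candidate
                break
            logger.warning("single-class fold; re-drawing folds with seed %d", rs + 1)
        else:
            folds = list(
                KFold(n_splits=config.cv_folds, shuffle=True, random_state=rs).split(X)
            )
            break
    if not folds:
        raise ValueError("could not draw folds with both classes present")

    fold_values = []
    for train, test in folds:
        est = _make_estimator(config)
        est.fit(X[train], y[train])
        if config.objective == "neg_mae":
            fold_values.append(-mean_absolute_error(y[test], est.predict(X[test])))
        else:
            decision = est.decision_function(X[test])
            fold_values.append(roc_auc_score(y[test], decision))
    fold_values = np.array(fold_values)
    return float(fold_values.mean()), fold_values


def evaluate_pipeline(
    dataset: SubjectDataset,
    spec: PipelineSpec,
    config: SearchConfig,
    cache: PipelineCache | None = None,
    subjects: Sequence[int] | None = None,
) -> Score:
    """Score one pipeline by seeded cross-validation on the search split."""
    if subjects is None:
        subjects = dataset.split_indices("search")
    feats = apply_pipeline(dataset, spec, subjects=subjects, cache=cache, seed=config.seed)
    X = features_matrix(feats)
    y = dataset.targets[np.asarray(subjects)]
    cv_seed = fold_seed(config.seed, spec.id)
    value, fold_values = score_features(X, y, config, cv_seed)
    return Score(pipeline_id=spec.id, value=value, fold_values=fold_values, seed=cv_seed)


def _build_kernel(config: SearchConfig):
    if config.kernel == "rbf":
        base = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
            length_scale=1.0, length_scale_bounds=(1e-3, 1e3)
        )
    else:
        base = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
            length_scale=1.0, length_scale_bounds=(1e-3, 1e3), nu=config.kernel_nu
        )
    if config.white_noise:
        base = base + WhiteKernel(noise_level=0.1, noise_level_bounds=(1e-8, 1e2))
    return base


def fit_gp(
    coords: np.ndarray,
    scores: np.ndarray,
    config: SearchConfig,
    previous: GPModelState | None = None,
) -> GPModelState:
    """Fit the GP surrogate, choosing kernel hyperparameters by maximizing log
    marginal likelihood.  On optimizer failure the previous hyperparameters
    are reused (logged)."""
    coords = np.asarray(coords, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(coords) < 2:
        raise ValueError("at least two evaluated pipelines are required to fit the GP")
    mean = float(scores.mean())
    sd = float(scores.std())
    if sd == 0.0:
        sd = 1.0
    z = (scores - mean) / sd
    gpr = GaussianProcessRegressor(
        kernel=_build_kernel(config),
        normalize_y=False,
        n_restarts_optimizer=1,
        random_state=config.seed % 2**31,
        alpha=1e-10,
    )
    try:
        with warnings.catch_warnings():
            # the white-noise level legitimately hits its lower bound on
            # noise-free synthetic landscapes
            warnings.simplefilter("ignore", ConvergenceWarning)
            gpr.fit(coords, z)
    except Exception as exc:  # pragma: no cover - defensive fallback
        logger.warning("GP hyperparameter optimization failed (%s); reusing previous", exc)
        kernel = previous.gpr.kernel_ if previous is not None else _build_kernel(config)
        gpr = GaussianProcessRegressor(kernel=kernel, optimizer=None, normalize_y=False)
        gpr.fit(coords, z)
    lower = coords.min(axis=0)
    upper = coords.max(axis=0)
    return GPModelState(
        gpr=gpr,
        train_coords=coords,
        train_scores=scores,
        score_mean=mean,
        score_sd=sd,
        bounds=np.vstack([lower, upper]),
    )


def ucb(mu, sigma, kappa: float):
    """Upper confidence bound acquisition, mu + kappa * sigma."""
    if np.any(np.asarray(sigma) < 0):
        raise ValueError("sigma must be non-negative")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    return mu + kappa * sigma


def _maximize_ucb(
    gp: GPModelState, kappa: float, seed: int, n_starts: int, bounds: np.ndarray
) -> np.ndarray:
    """Seeded multi-start pattern search for the continuous UCB maximum.

    Batched across starts so each step needs one GP prediction call; shrinks
    the step when no axis move improves.  Gradient-free and deterministic.
    """
    rng = np.random.default_rng(seed)
    lower, upper = bounds[0], bounds[1]
    span = np.where(upper > lower, upper - lower, 1.0)
    pts = lower + rng.uniform(size=(n_starts, len(lower))) * (upper - lower)
    d = pts.shape[1]
    steps = np.full(n_starts, 0.25)

    def acq(x: np.ndarray) -> np.ndarray:
        mu, sd = gp.mu_sigma(x)
        return ucb(mu, sd, kappa)

    best_val = acq(pts)
    for _ in range(30):
        moves = np.zeros((n_starts, 2 * d, d))
        for ax in range(d):
            moves[:, 2 * ax, ax] = 1.0
            moves[:, 2 * ax + 1, ax] = -1.0
        cand = pts[:, None, :] + moves * (steps[:, None, None] * span[None, None, :])
        cand = np.clip(cand, lower, upper)
        vals = acq(cand.reshape(-1, d)).reshape(n_starts, 2 * d)
        arg = vals.argmax(axis=1)
        improved = vals[np.arange(n_starts), arg] > best_val + 1e-12
        pts[improved] = cand[np.arange(n_starts), arg][improved]
        best_val[improved] = vals[np.arange(n_starts), arg][improved]
        steps[~improved] *= 0.5
        if np.all(steps < 1e-4):
            break
    return pts[int(np.argmax(best_val))]


def propose_next(
    gp: GPModelState,
    space: EmbeddedSpace,
    sampled: set[int],
    kappa: float,
    seed: int = 0,
    grid: PipelineGrid | None = None,
    n_starts: int = 16,
):
    """Maximize UCB over the embedding's bounding box, then snap to the
    nearest not-yet-sampled pipeline (ties by pipeline id).

    Returns the chosen pipeline id, or its PipelineSpec when ``grid`` is given.
    """
    unsampled = np.array([p for p in space.pipeline_ids if int(p) not in sampled], dtype=int)
    if len(unsampled) == 0:
        raise RuntimeError("space exhausted: every pipeline has been sampled")
    x_star = _maximize_ucb(gp, kappa, seed, n_starts, gp.bounds)
    coords = space.coords[unsampled]
    dist = np.linalg.norm(coords - x_star[None, :], axis=1)
    chosen = int(unsampled[np.lexsort((unsampled, dist))[0]])
    if grid is not None:
        return grid[chosen]
    return chosen


def run_search(
    dataset: SubjectDataset | None,
    grid: PipelineGrid,
    space: EmbeddedSpace,
    config: SearchConfig,
    cache: PipelineCache | None = None,
    evaluator: Callable[[PipelineSpec], Score] | None = None,
) -> SearchTrace:
    """Burn-in then acquisition-driven sampling; never re-evaluates a pipeline.

    ``evaluator`` overrides cross-validated pipeline scoring (used for
    synthetic landscapes and custom objectives); by default pipelines are
    scored with :func:`evaluate_pipeline` on the dataset's search split.  A
    failed evaluation is imputed as the worst observed score minus one sd of
    the observed scores and flagged, so the search can continue.
    """
    P = len(grid)
    if config.n_burn_in + config.n_iterations > P:
        raise ValueError(
            f"budget {config.n_burn_in}+{config.n_iterations} exceeds grid size {P}"
        )
    cache = cache if cache is not None else PipelineCache()

    def default_evaluator(spec: PipelineSpec) -> Score:
        return evaluate_pipeline(dataset, spec, config, cache=cache)

    evaluate = evaluator if evaluator is not None else default_evaluator

    def safe_evaluate(spec: PipelineSpec, observed: list[float]) -> Score:
        try:
            return evaluate(spec)
        except Exception as exc:
            if not observed:
                raise
            imputed = min(observed) - (np.std(observed) if len(observed) > 1 else 1.0)
            logger.warning(
                "pipeline %d failed (%s); imputing %.4f", spec.id, exc, imputed
            )
            return Score(
                pipeline_id=spec.id,
                value=float(imputed),
                fold_values=np.array([]),
                seed=fold_seed(config.seed, spec.id),
                flagged=True,
            )

    rng = np.random.default_rng(config.seed)
    burn_ids = rng.choice(P, size=config.n_burn_in, replace=False)
    trace = SearchTrace(config=config)
    sampled: set[int] = set()
    for it, pid in enumerate(burn_ids):
        spec = grid[int(pid)]
        score = safe_evaluate(spec, [e.score.value for e in trace.entries])
        trace.entries.append(
            TraceEntry(
                iteration=it,
                pipeline_id=spec.id,
                coords=space.coords[spec.id].copy(),
                score=score,
                acquisition=float("nan"),
                phase="burn_in",
            )
        )
        sampled.add(spec.id)

    gp: GPModelState | None = None
    for it in range(config.n_iterations):
        coords = np.array([e.coords for e in trace.entries])
        scores = np.array([e.score.value for e in trace.entries])
        gp = fit_gp(coords, scores, config, previous=gp)
        spec = propose_next(
            gp,
            space,
            sampled,
            config.kappa,
            seed=fold_seed(config.seed, 100_000 + it),
            grid=grid,
            n_starts=config.n_acq_starts,
        )
        mu, sd = gp.mu_sigma(space.coords[spec.id])
        acq_value = float(ucb(mu, sd, config.kappa)[0])
        score = safe_evaluate(spec, [e.score.value for e in trace.entries])
        trace.entries.append(
            TraceEntry(
                iteration=config.n_burn_in + it,
                pipeline_id=spec.id,
                coords=space.coords[spec.id].copy(),
                score=score,
                acquisition=acq_value,
                phase="active",
            )
        )
        sampled.add(spec.id)

    coords = np.array([e.coords for e in trace.entries])
    scores = np.array([e.score.value for e in trace.entries])
    trace.gp = fit_gp(coords, scores, config, previous=gp)
    return trace


def predict_landscape(gp: GPModelState, space: EmbeddedSpace) -> LandscapeEstimate:
    """GP posterior mean and sd at every pipeline coordinate."""
    mu, sigma = gp.mu_sigma(space.coords)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sigma))):
        raise FloatingPointError("GP landscape prediction produced non-finite values")
    return LandscapeEstimate(mu=mu, sigma=sigma, pipeline_ids=space.pipeline_ids.copy())
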
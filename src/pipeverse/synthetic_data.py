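"""Seeded synthetic cohorts with a planted target signal in connectivity.

The generator emulates the data regime a multiverse pipeline study consumes:
per-subject region x time BOLD-like series, a continuous (age-like) or binary
(diagnosis-like) target, and several *data variants* of each subject that stand
in for preprocessing alternatives (e.g. motion regression vs global signal
regression).  The target modulates a fixed random subset of region-pair
couplings, so downstream pipelines can in principle recover it, and variants
share the subject's underlying signal while differing by structured
perturbations (a global component retained or removed, plus independent noise).

Time series are stationary multivariate normal draws; no autocorrelation or
hemodynamics are simulated.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

SPLIT_LABELS = ("space", "search", "holdout")

#: SD of the standardized latent modulator entering the coupling matrix.  Kept
#: well below the +/-1 correlation bound so the planted effect stays in the
#: linear, positive-definite regime across the default signal-strength range.
MODULATOR_SD = 0.2

#: variant labels used when a two-variant regression-style cohort is generated
DEFAULT_VARIANT_LABELS = ("motion_regression", "global_signal_regression")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Configuration of a synthetic cohort.

    Parameters
    ----------
    n_subjects, n_regions, n_timepoints, n_variants:
        Cohort dimensions; all must be >= 2.
    signal_edges_fraction:
        Fraction of region pairs whose coupling carries the target signal.
    signal_strength:
        Slope of the target -> coupling modulation (regression) or the
        group-mean coupling offset (classification).
    variant_perturbation_sd:
        SD of independent noise added to each data variant.
    global_component_sd:
        SD of a shared global time course retained in odd variants and removed
        in even ones (emulating global signal regression).
    task:
        ``"regression"`` (continuous age-like target) or ``"classification"``
        (balanced binary target).
    seed:
        Non-negative integer; identical config + seed gives bit-identical data.
    variant_labels:
        Optional explicit labels; defaults to motion/global-signal regression
        for two variants.
    """

    n_subjects: int = 100
    n_regions: int = 30
    n_timepoints: int = 200
    n_variants: int = 2
    signal_edges_fraction: float = 0.15
    signal_strength: float = 0.5
    variant_perturbation_sd: float = 0.3
    global_component_sd: float = 0.5
    task: str = "regression"
    seed: int = 0
    variant_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_regions", "n_timepoints", "n_variants"):
            if int(getattr(self, name)) < 2:
                raise ValueError(f"{name} must be >= 2, got {getattr(self, name)}")
        if not (0.0 < self.signal_edges_fraction <= 1.0):
            raise ValueError("signal_edges_fraction must lie in (0, 1]")
        if self.signal_strength < 0 or self.variant_perturbation_sd < 0 or self.global_component_sd < 0:
            raise ValueError("signal_strength and noise SDs must be non-negative")
        if self.task not in ("regression", "classification"):
            raise ValueError("task must be 'regression' or 'classification'")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if self.variant_labels is not None and len(self.variant_labels) != self.n_variants:
            raise ValueError("variant_labels length must equal n_variants")
        n_pairs = self.n_regions * (self.n_regions - 1) // 2
        if int(round(self.signal_edges_fraction * n_pairs)) < 1:
            raise ValueError(
                "impossible config: signal_edges_fraction * region pairs < 1 "
                f"({self.signal_edges_fraction} * {n_pairs})"
            )

    def resolved_variant_labels(self) -> tuple[str, ...]:
        if self.variant_labels is not None:
            return tuple(self.variant_labels)
        if self.n_variants == 2:
            return DEFAULT_VARIANT_LABELS
        return tuple(f"variant_{i}" for i in range(self.n_variants))


@dataclass
class SubjectDataset:
    """Per-variant subject data plus targets, communities and split labels.

    ``variants`` maps a variant label to an array of shape
    ``(n_subjects, n_regions_v, n_timepoints)`` when ``data_kind`` is
    ``"timeseries"`` or ``(n_subjects, n_regions_v, n_regions_v)`` when
    pre-computed connectivity is supplied.  Region counts may differ between
    variants (multi-parcellation cohorts); subject count and ordering may not.
    """

    variants: dict[str, np.ndarray]
    targets: np.ndarray
    task: str
    communities: dict[str, np.ndarray]
    subject_ids: list[str] = field(default_factory=list)
    split: np.ndarray | None = None
    data_kind: str = "timeseries"
    config: SyntheticCohortConfig | None = None

    def __post_init__(self) -> None:
        counts = {v.shape[0] for v in self.variants.values()}
        if len(counts) != 1:
            raise ValueError("every variant must hold the same subject count")
        (n,) = counts
        if len(self.targets) != n:
            raise ValueError("targets length must match subject count")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i:04d}" for i in range(n)]

    @property
    def n_subjects(self) -> int:
        return len(self.targets)

    def split_indices(self, label: str) -> np.ndarray:
        if self.split is None:
            raise ValueError("dataset has no split labels; call split_dataset first")
        if label not in SPLIT_LABELS:
            raise ValueError(f"unknown split label {label!r}; expected one of {SPLIT_LABELS}")
        return np.flatnonzero(self.split == label)


def _base_correlation(rng: np.random.Generator, n_regions: int) -> np.ndarray:
    """Random well-conditioned correlation matrix used as the shared coupling."""
    w = rng.standard_normal((n_regions, n_regions))
    m = w @ w.T / n_regions
    d = np.sqrt(np.diag(m))
    c = m / np.outer(d, d)
    sigma = 0.3 * c
    np.fill_diagonal(sigma, 1.0)
    return sigma


def _ensure_positive_definite(sigma: np.ndarray, step: float = 1e-6) -> tuple[np.ndarray, float]:
    """Repair a symmetric matrix by the smallest diagonal loading (in ``step``
    increments) that lifts its minimum eigenvalue above 1e-8."""
    min_eig = float(np.linalg.eigvalsh(sigma)[0])
    if min_eig > 1e-8:
        return sigma, 0.0
    load = math.ceil((1e-8 - min_eig) / step) * step
    out = sigma + load * np.eye(sigma.shape[0])
    logger.debug("coupling repaired by diagonal loading %.2e", load)
    return out, load


def _signal_edge_index(rng: np.random.Generator, n_regions: int, fraction: float) -> np.ndarray:
    n_pairs = n_regions * (n_regions - 1) // 2
    k = int(round(fraction * n_pairs))
    return np.sort(rng.choice(n_pairs, size=k, replace=False))


def region_communities(n_regions: int, n_communities: int = 7) -> np.ndarray:
    """Contiguous community assignment emulating a seven-network parcellation."""
    k = min(n_communities, n_regions)
    return (np.arange(n_regions) * k) // n_regions


def _draw_targets(rng: np.random.Generator, config: SyntheticCohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Return (targets, effect) where effect is the standardized modulator."""
    n = config.n_subjects
    if config.task == "regression":
        latent = rng.standard_normal(n)
        targets = 19.0 + 3.0 * latent  # age-like scale (years)
        return targets, MODULATOR_SD * latent
    labels = np.zeros(n)
    labels[: n // 2] = 1.0
    rng.shuffle(labels)
    return labels, 2.0 * MODULATOR_SD * (labels - 0.5)


def _subject_series(
    rng: np.random.Generator,
    base: np.ndarray,
    signal_idx: np.ndarray,
    effect: float,
    strength: float,
    n_timepoints: int,
) -> np.ndarray:
    n_regions = base.shape[0]
    iu = np.triu_indices(n_regions, k=1)
    sigma = base.copy()
    rows, cols = iu[0][signal_idx], iu[1][signal_idx]
    sigma[rows, cols] += strength * effect
    sigma[cols, rows] = sigma[rows, cols]
    sigma, _ = _ensure_positive_definite(sigma)
    chol = np.linalg.cholesky(sigma)
    return chol @ rng.standard_normal((n_regions, n_timepoints))


def generate_cohort(config: SyntheticCohortConfig) -> SubjectDataset:
    """Generate a seeded cohort with a planted connectivity-target association.

    For each subject a latent target draws a coupling matrix (base correlation
    plus ``signal_strength * effect`` on a fixed random edge subset, repaired to
    positive definite when needed), from which stationary multivariate-normal
    time series are sampled.  Variant ``v`` adds a shared global time course
    (retained for even ``v``, removed for odd ``v``) and independent noise.
    """
    rng = np.random.default_rng(config.seed)
    labels = config.resolved_variant_labels()
    targets, effect = _draw_targets(rng, config)
    base = _base_correlation(rng, config.n_regions)
    signal_idx = _signal_edge_index(rng, config.n_regions, config.signal_edges_fraction)

    shape = (config.n_subjects, config.n_regions, config.n_timepoints)
    data = {label: np.empty(shape) for label in labels}
    for s in range(config.n_subjects):
        series = _subject_series(
            rng, base, signal_idx, float(effect[s]), config.signal_strength, config.n_timepoints
        )
        global_comp = rng.standard_normal(config.n_timepoints) * config.global_component_sd
        for v, label in enumerate(labels):
            noise = rng.standard_normal(series.shape) * config.variant_perturbation_sd
            retained = global_comp if v % 2 == 0 else 0.0
            data[label][s] = series + retained + noise

    comm = region_communities(config.n_regions)
    return SubjectDataset(
        variants=data,
        targets=targets,
        task=config.task,
        communities={label: comm.copy() for label in labels},
        config=config,
    )


def signal_edge_pairs(config: SyntheticCohortConfig) -> np.ndarray:
    """Return the (i, j) region pairs carrying the planted signal.

    Replays the generator's seeded draws, so it is exact for the cohort built
    from the same config.
    """
    rng = np.random.default_rng(config.seed)
    _draw_targets(rng, config)
    _base_correlation(rng, config.n_regions)
    idx = _signal_edge_index(rng, config.n_regions, config.signal_edges_fraction)
    iu = np.triu_indices(config.n_regions, k=1)
    return np.column_stack([iu[0][idx], iu[1][idx]])


def generate_multifactor_cohort(
    config: SyntheticCohortConfig,
    preproc_levels: Sequence[str],
    strategy_levels: Sequence[str],
    parcellation_regions: Mapping[str, int],
) -> SubjectDataset:
    """Cohort whose variants span preprocessing x strategy x parcellation combos.

    Emulates a classification-style multiverse where every pipeline picks one
    already-materialized data variant: each parcellation has its own region
    count and its own base coupling (modulated by the same subject effect);
    strategies containing ``"noglobal"`` retain the shared global component
    (no global signal regression), the rest remove it; each preprocessing
    suite contributes independent perturbation noise.  Variant labels are
    ``"{preproc}|{strategy}|{parcellation}"``.
    """
    master = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    targets, effect = _draw_targets(master, config)

    variants: dict[str, np.ndarray] = {}
    communities: dict[str, np.ndarray] = {}
    for p_idx, (parc, n_regions) in enumerate(parcellation_regions.items()):
        if n_regions < 2:
            raise ValueError(f"parcellation {parc!r} must have >= 2 regions")
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1 + p_idx]))
        base = _base_correlation(rng, n_regions)
        n_pairs = n_regions * (n_regions - 1) // 2
        fraction = max(config.signal_edges_fraction, 1.5 / n_pairs)
        signal_idx = _signal_edge_index(rng, n_regions, fraction)
        series = np.empty((config.n_subjects, n_regions, config.n_timepoints))
        globals_ = np.empty((config.n_subjects, config.n_timepoints))
        for s in range(config.n_subjects):
            series[s] = _subject_series(
                rng, base, signal_idx, float(effect[s]), config.signal_strength, config.n_timepoints
            )
            globals_[s] = rng.standard_normal(config.n_timepoints) * config.global_component_sd
        comm = region_communities(n_regions)
        for pp_idx, preproc in enumerate(preproc_levels):
            for st_idx, strategy in enumerate(strategy_levels):
                vrng = np.random.default_rng(
                    np.random.SeedSequence([config.seed, 1000 + p_idx, pp_idx, st_idx])
                )
                noise = vrng.standard_normal(series.shape) * config.variant_perturbation_sd
                retain_global = "noglobal" in strategy
                block = series + noise
                if retain_global:
                    block = block + globals_[:, None, :]
                label = f"{preproc}|{strategy}|{parc}"
                variants[label] = block
                communities[label] = comm.copy()

    return SubjectDataset(
        variants=variants,
        targets=targets,
        task=config.task,
        communities=communities,
        config=config,
    )


def _sizes_from_fractions(n: int, fractions: Sequence[float]) -> list[int]:
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1 (got {sum(fractions)})")
    ideal = [f * n for f in fractions]
    sizes = [int(math.floor(x)) for x in ideal]
    remainders = [x - s for x, s in zip(ideal, sizes)]
    for _ in range(n - sum(sizes)):
        i = int(np.argmax(remainders))
        sizes[i] += 1
        remainders[i] = -1.0
    return sizes


def _allocate_stratified(
    rng: np.random.Generator, targets: np.ndarray, sizes: Sequence[int]
) -> np.ndarray:
    """Assign split labels keeping per-class proportions within +/-1 subject."""
    n = len(targets)
    assignment = np.empty(n, dtype=object)
    classes, inverse = np.unique(targets, return_inverse=True)
    remaining = list(sizes)
    class_order = np.argsort([-np.sum(inverse == c) for c in range(len(classes))])
    for rank, c in enumerate(class_order):
        members = np.flatnonzero(inverse == c)
        rng.shuffle(members)
        if rank < len(class_order) - 1:
            ideal = [len(members) * s / n for s in sizes]
            take = [int(math.floor(x)) for x in ideal]
            rem = [x - t for x, t in zip(ideal, take)]
            order = np.argsort(rem)[::-1]
            for i in order:
                if sum(take) >= len(members):
                    break
                if take[i] < remaining[i]:
                    take[i] += 1
        else:
            take = list(remaining)
        pos = 0
        for i, t in enumerate(take):
            t = min(t, remaining[i])
            assignment[members[pos : pos + t]] = SPLIT_LABELS[i]
            remaining[i] -= t
            pos += t
        # any leftovers (rounding under constraints) go to the emptiest split
        for m in members[pos:]:
            i = int(np.argmax(remaining))
            assignment[m] = SPLIT_LABELS[i]
            remaining[i] -= 1
    return assignment.astype(str)


def split_dataset(
    dataset: SubjectDataset,
    fractions: Sequence[float] | None = None,
    sizes: Sequence[int] | None = None,
    stratify: bool = False,
    seed: int = 0,
) -> SubjectDataset:
    """Assign space/search/holdout labels; absolute ``sizes`` take precedence.

    The three-way split mirrors the lock-box design: one part builds the
    pipeline space, one drives the active search, and one is held out for the
    final score of the selected pipeline.  Stratification keeps per-class
    proportions in each split within one subject of the global proportion.
    """
    n = dataset.n_subjects
    if sizes is not None:
        sizes = [int(s) for s in sizes]
        if sum(sizes) != n:
            raise ValueError(f"sizes {sizes} must sum to the subject count {n}")
    elif fractions is not None:
        sizes = _sizes_from_fractions(n, fractions)
    else:
        raise ValueError("either fractions or sizes must be given")
    if len(sizes) != 3:
        raise ValueError("exactly three splits (space, search, holdout) are required")
    if any(s <= 0 for s in sizes):
        raise ValueError(f"every split must be non-empty, got sizes {sizes}")

    rng = np.random.default_rng(seed)
    if stratify:
        labels = _allocate_stratified(rng, dataset.targets, sizes)
    else:
        order = rng.permutation(n)
        labels = np.empty(n, dtype=object)
        pos = 0
        for size, name in zip(sizes, SPLIT_LABELS):
            labels[order[pos : pos + size]] = name
            pos += size
        labels = labels.astype(str)

    if dataset.task == "classification":
        for name in SPLIT_LABELS:
            split_targets = dataset.targets[labels == name]
            if len(np.unique(split_targets)) < 2:
                if stratify:
                    raise ValueError(f"split {name!r} lost a class despite stratification")
                logger.warning("split %r contains a single class; consider stratify=True", name)

    return dataclasses.replace(dataset, split=labels)
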
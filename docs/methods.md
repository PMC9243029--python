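# Methods

## The guided-multiverse model

`pipeverse` treats an analysis multiverse — the Cartesian product of discrete
processing choices — as a landscape over a continuous low-dimensional space,
and estimates that landscape from a small number of evaluations.

**Pipeline signatures.** For pipeline *p* applied to the space-split subjects,
the signature is the vector of cosine similarities between every unordered
pair of subjects' feature vectors (length n(n−1)/2, self-pairs excluded).
Two pipelines with near-identical signatures induce the same
individual-differences structure and will perform near-identically on any
subject-level prediction task; that is the working assumption that makes the
space searchable. The table orientation is rows = pipelines,
columns = pairs; the transpose is an equivalent presentation.

**Embedding.** Pipeline–pipeline dissimilarity is the Euclidean distance
between signature rows (correlation distance is available as an option; the
choice matters little because signatures are bounded and equal-length).
Metric MDS (SMACOF, classical Torgerson initialization, `eps = 1e-9`,
≤1000 iterations) minimizes stress on these dissimilarities; PCA of the
row-centered table is the linear alternative. Both are deterministic given
the seed. d = 2 by default — higher d buys fidelity at the cost of a harder
acquisition problem. Additional embedding algorithms (t-SNE, UMAP, …) can be
attached through `pipeverse.space.register_embedding` without core changes.

**Embedding quality.** `neighborhood_preservation` is the mean fraction of
each pipeline's k nearest neighbors (original dissimilarity) that remain
among its k nearest embedded neighbors; 1 for an isometry, ≈ k/(P−1) for an
uninformative embedding; ties broken by pipeline id. Its complement is a
dissimilarity score.

**Scoring.** A pipeline's score is 5-fold cross-validated predictive accuracy
on the search split: support vector regression (RBF, C = 1, ε = 0.1) scored
by negative mean absolute error in target units for continuous targets;
L2 logistic regression (C = 1) scored by AUC of the decision function for
binary targets. Features are z-scored inside each training fold. Folds are
shuffled with a seed derived from (global seed, pipeline id), so a pipeline's
score is identical whether it is reached by a search trace or by exhaustive
evaluation, and is independent of sampling order. Estimator hyperparameters
are fixed at these conventional defaults; the estimator family, not its
tuning, is the object of study.

**Surrogate.** Scores are z-scored online and fitted by a Gaussian process
with kernel `C · Matern(ν = 2.5) + White` (RBF available), hyperparameters
re-chosen each iteration by maximizing log marginal likelihood (one restart).
The white-noise component absorbs cross-validation noise; ν = 2.5 gives a
once-differentiable surface — flexible but not rough. Predictions are
un-z-scored on output; the reported σ includes the fitted noise level.

**Acquisition.** Upper confidence bound, UCB(x) = μ(x) + κ·σ(x). κ ≥ 0 is the
exploration knob: κ = 10 (default) drives uncertainty down across the whole
space and yields a faithful landscape estimate; κ = 0.1 converges onto an
estimated optimum in few samples at the cost of global accuracy. The
continuous UCB maximum over the embedding's bounding box is found by a
seeded 16-start pattern (compass) search — gradient-free, batched so each
step costs one GP prediction call, deterministic — and the proposal snaps to
the nearest *unevaluated* pipeline coordinate (ties by pipeline id). Snapping
only to unevaluated pipelines guarantees progress and means no pipeline is
ever scored twice within a run. In the exploitative regime the snapped choice
is almost always the acquisition-optimal candidate; in the exploratory regime
the σ-dominated acquisition surface plateaus between candidates, so the
snapped choice can be a near-tie neighbor of the discrete optimum rather than
the optimum itself — the acquisition value lost is small, and the search
behavior (coverage, landscape recovery) is unaffected.

**Loop.** 10 burn-in pipelines drawn uniformly without replacement, then 50
acquisition iterations (both configurable; the budget must not exceed the
grid). A failed pipeline evaluation is imputed as the worst observed score
minus one standard deviation and flagged — failing pipelines should look
poor, not abort the run. The final GP is refitted on all evaluations and
exposed as a landscape estimate (μ, σ at every pipeline coordinate).

**Evaluation machinery.** `exhaustive_evaluate` produces the empirical
landscape; `space_correlation` the Spearman ρ between estimated and empirical
scores (average ranks for ties; NaN for constant vectors); `extract_optima`
the GP-estimated and best-sampled optima (ties by id); `repeat_search` runs
R independent repetitions with seeds base + r — distinct by construction —
reporting per-repetition optima, lock-box scores and ρ, with failed
repetitions reported rather than dropped. `holdout_score` refits the
estimator on the entire search split and scores the selected pipeline once
on the untouched hold-out split.

## Pipeline grids

*Regression design* (544 default): data variant
{motion_regression, global_signal_regression} × 17 proportional-threshold
sparsities × 16 nodal graph metrics. Connectivity is Pearson correlation;
thresholding keeps the ⌈s·E⌉ strongest of the E = n(n−1)/2 unique edges
(weights preserved, no binarization — several metrics, strength foremost, are
degenerate on binary graphs at fixed density; ties at the cut break by
lexicographic pair order); the feature vector is one nodal value per region.

The 17 sparsities {0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.08, 0.10, 0.125,
0.15, 0.175, 0.20, 0.225, 0.25, 0.275, 0.30, 0.40} span very sparse to dense
graphs. The 16-metric registry (configurable) covers simple and higher-level
nodal features: strength, degree, betweenness, eigenvector, closeness,
pagerank and subgraph centrality, clustering coefficient, local efficiency,
k-coreness, participation coefficient, module-degree z-score, gateway
coefficients (degree- and betweenness-based), within-community strength, and
a Louvain-based nodal modularity contribution. Metrics operate on weight
magnitudes with path lengths 1/|w|. Community-dependent metrics use a fixed
prior assignment (the generator emulates a seven-network parcellation);
Louvain community detection is stochastic, so it is seeded from
(global seed, pipeline id) — landscapes are reproducible and independent of
sampling order. The gateway coefficient follows the participation-coefficient
form with each community term down-weighted by the node's gateway criticality
(its share of the module-to-community connection strength times its relative
centrality within the module).

*Classification design* (384 default): preprocessing suite (4) × processing
strategy (band-pass filtering ± global signal regression, 4) × parcellation
(6, differing region counts) × connectivity estimator {covariance,
correlation, partial correlation, tangent}. The first three factors select an
already-materialized data variant; the estimator maps its time series to a
matrix whose strict lower triangle is the feature vector. Partial correlation
is −Ω_ij/√(Ω_ii·Ω_jj) from the precision Ω of the (ridge-regularized when the
condition number exceeds 1e12, λ = 1e-6 × mean diagonal) covariance. The
tangent estimator computes logm(ref^{−1/2} C ref^{−1/2}); the reference is
the Euclidean mean of the group covariances projected to positive definite
(eigenvalue floor 1e-10), with the affine-invariant (Karcher) geometric mean
available as an option — both are accepted conventions, and the Euclidean
mean is cheaper and stable on small samples.

## Synthetic cohorts

The generator emulates the statistical regime the method assumes, not the
physics of the measurement:

- Each subject has a latent standardized target (age-like, reported as
  19 + 3·z years, or a balanced binary label). A base coupling matrix (random
  correlation matrix, off-diagonal shrunk to 0.3) is shared by all subjects;
  `signal_strength` times the subject's latent modulator is added to a fixed
  random `signal_edges_fraction` of couplings (a group offset for binary
  targets). The modulator has SD 0.2 so the default strength range stays
  inside the linear, positive-definite regime of correlation-based
  connectivity; matrices that still lose positive definiteness are repaired
  by the smallest sufficient diagonal loading in 1e-6 steps (logged).
- Time series are stationary multivariate normal draws from the implied
  covariance — no autocorrelation, hemodynamics or motion; conclusions about
  temporal structure are out of reach of these fixtures by design.
- Data variants share the subject's series and differ by a global time course
  (SD `global_component_sd`, retained in variants emulating no global signal
  regression, removed otherwise) plus independent noise
  (SD `variant_perturbation_sd`). This reproduces the one property the
  similarity signature relies on: within-subject agreement across variants
  exceeds between-subject agreement within a variant.
- Multi-parcellation cohorts draw an independent base coupling per
  parcellation (region counts differ) modulated by the same subject effect.
- Defaults (100 subjects, 30 regions, 200 timepoints, 15 % signal edges,
  strength 0.5, perturbation SD 0.3, global SD 0.5) give a planted effect
  that is clearly detectable (target ↔ signal-edge connectivity correlation
  ≈ 0.9 at n = 100) without saturating, and monotone in `signal_strength`
  over {0, 0.25, 0.5}.
- Everything is driven by one integer seed; identical config + seed gives
  bit-identical cohorts, tables, embeddings and traces.

Passing tests on these cohorts demonstrate the machinery — signature
geometry, surrogate search, split hygiene — under the generator's
assumptions; they do not certify performance on real neuroimaging data,
whose noise structure, site effects and preprocessing interactions the
generator deliberately omits.

The three-way split (space / search / lock-box) may be given as fractions or
absolute sizes; sizes take precedence (largest-remainder rounding for
fractions), and stratified splitting keeps per-class proportions within one
subject of the global proportion in every split.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the full default grids against
cohorts with reduced region counts (12 regions for the 544-pipeline
similarity table, 8–18 for the 384-pipeline table, 60 regions for the
default-budget search demonstration) and validate search behavior on a
128-pipeline synthetic landscape with a known two-peak score surface. These
sizes exercise every code path at desk scale; all quantities they print are
recomputed at run time.

## Known limitations

- The similarity signature assumes subject-level feature vectors of equal
  length within a pipeline; cross-modal pipelines are representable only
  through their signatures, which is the point, but no adapter for real
  acquisition formats beyond delimited text is included.
- GP inference is exact (O(m³) in evaluations); fine for the intended tens
  of evaluations, not for thousands.
- Only UCB acquisition is provided; expected improvement and batch
  acquisition are out of scope.
- With κ in the exploitative regime the search can settle on a local optimum;
  that is a property of the method, surfaced deliberately by the κ-contrast
  checks.
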
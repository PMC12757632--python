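# Methods

## Problem setting

A functional connectome (FC) is the m × m Pearson-correlation matrix of m
parcellated fMRI region time series over T frames. FCs are symmetric,
unit-diagonal, entrywise in [−1, 1], positive semidefinite, and — because
correlation mean-centers each region — of rank at most min(m, T−1). Subject
identification ("fingerprinting") asks whether the FC from one scanning
session is closer, under some matrix dissimilarity, to the same subject's
other session than to any other subject's. The package implements the
dissimilarities, the 1-NN identification rule, the experiment battery
around them, and a synthetic cohort generator; this note records the models
and the choices behind them.

## The measures

Entrywise baselines: Euclidean ‖A−B‖_F; Pearson distance 1 − r between the
strict-upper-triangle vectorizations. The diagonal is excluded from the
Pearson vectorization because a correlation FC's diagonal is identically 1:
including it would only shrink the statistic toward a constant. Note the
Pearson distance is a bounded dissimilarity, not a metric — it is excluded
from triangle-inequality checks.

Manifold measures, all evaluated through one validated eigendecomposition
layer (`linalg`):

* affine-invariant (AIRM): d(A,B) = ‖log(A^{−1/2} B A^{−1/2})‖_F
* Log-Euclidean: ‖log A − log B‖_F
* Bures–Wasserstein (BW): (tr A + tr B − 2 tr(A^{1/2} B A^{1/2})^{1/2})^{1/2}
* Alpha Procrustes: (1/α) min_{U orthogonal} ‖A^α − B^α U‖_F, α ∈ (0,1)
* Alpha-Z divergence: Φ(A,B) = tr((1−α)A + αB) − tr (A^{(1−α)/2z} B^{α/z}
  A^{(1−α)/2z})^z, α ∈ (0,1), z > 0

AIRM and Log-Euclidean require positive-definite operands; both accept a
ridge τ ≥ 0 applied to *both* operands (A+τI, B+τI) before evaluation. BW,
Alpha Procrustes, and Alpha-Z never invert — every fractional power used is
positive, with the convention 0^p = 0 — so they take raw PSD input and no τ
is applied to them. This asymmetry of treatment is deliberate: it is the
substantive difference between the two families, and regularizing the
inversion-free measures would only blur it.

The Alpha Procrustes minimum over orthogonal U is eliminated analytically:
by the polar-decomposition solution of the orthogonal Procrustes problem,
min_U ‖A^α − B^α U‖_F² = tr A^{2α} + tr B^{2α} − 2 tr(A^α B^{2α} A^α)^{1/2}.
The 1/α prefactor is a normalization choice: with it, the family satisfies
d_{1/2} = 2·d_BW exactly and converges to the Log-Euclidean distance as
α → 0; without it both anchor points acquire a spurious factor α. The
package treats those two identities as the defining anchors of the family
(they are verified to 1e-8 and 1e-3 respectively in the test suite).

Φ is asymmetric in its arguments when α ≠ 1/2. The package fixes the
convention that the first argument is always the train-session matrix, and
every result object records the metric parameters used, so the direction is
reproducible. Φ(A,A) = 0, Φ ≥ 0, and Φ satisfies in-betweenness with
respect to the matrix power mean μ_p(t;A,B) = (tA^p + (1−t)B^p)^{1/p} for
p ∈ [1/2, 1] — all property-tested, including on rank-deficient operands.

Fixed parameter defaults: α = 0.99, z = 1 for Alpha-Z; α = 0.6 for Alpha
Procrustes. These are single fixed choices used across all experiments —
the point of the divergence is precisely that it does not need per-dataset
tuning. For AIRM/Log-Euclidean the CLI refuses to default τ: the τ sweep
experiment exists because the choice is consequential, so it must be
explicit.

## Numerical choices

* Inputs are symmetrized as (M+Mᵀ)/2 when the asymmetry is below
  1e-10·max(1, |M|_∞); larger asymmetry is rejected (it indicates a garbled
  file, not rounding).
* Eigenvalues in [−1e-8·max(λ_max, 1), 0) are clipped to 0 — finite-sample
  correlation matrices are PSD only up to rounding; anything more negative
  is a hard "not PSD" error.
* Effective rank counts eigenvalues above 1e-8·λ_max by default. The
  tolerance is a package convention; rank statements in the tests use it
  consistently.
* For the log-based measures at τ = 0, eigenvalues below an explicit floor
  (default 1e-10) are raised to the floor with a warning. This lets users
  probe the rank-deficient failure mode (the low-τ identification collapse)
  without crashes, while making the distortion visible in logs. Setting the
  floor to 0 turns singular operands into errors advising τ > 0.
* Squared distances of the trace-difference form (BW, Alpha Procrustes) are
  only accurate to ~machine-epsilon times the operand trace; values below
  1e-12·(tr A + tr B) are treated as exactly 0, and negative values beyond
  1e-6·scale raise instead of being silently clipped.
* Batch pairwise evaluation caches per-matrix spectral factors (A^{1/2},
  log A, A^α, …) per side, so an N × N table costs O(N·m³) decompositions
  plus O(N²) matrix products — the table for N = 60, m = 120 takes seconds.
* 1-NN argmin ties break to the lowest index, deterministically. The
  all-equal distance table therefore yields an ID rate of exactly 1/3 on
  three subjects — documented and tested rather than randomized away.

## Identification and experiments

The ID rate is the mean of two directional accuracies over the N × N
cross-session table: matching test columns to train rows and vice versa.
There is no self-match exclusion — rows and columns are different sessions,
and matching a subject across sessions is the success criterion.

The null model permutes the test-session subject labels over a *fixed*
divergence matrix: predictions never change under relabeling, only the
correctness bookkeeping does, so each of thousands of permutations costs
O(N). Under uniform permutation the expected null rate is exactly 1/N.
Permutation p-values use the add-one estimator (1 + #{null ≥ observed}) /
(n_perm + 1), never exactly zero. Note that 1/N at realistic N is well
below 10%: a null rate near 10% cannot arise from uniform label
permutation at cohort scale, so reports of ~10% chance levels imply some
other chance model; this package implements the uniform-permutation null
exactly.

Ranking stability compares per-network ID-rate rankings across parcellation
granularities by Spearman correlation (average ranks for ties, via scipy),
with a one-sided (≥) permutation test — exact enumeration of all n!
permutations when a profile has ≤ 8 networks (7! = 5040), seeded Monte
Carlo with the add-one estimator otherwise. Benjamini–Hochberg FDR is
applied jointly across the full condition × granularity grid, the natural
multiple-comparison family for the stability matrix; significance is
q < 0.05. The BH step-up is a few lines of numpy, verified in tests against
an independently enumerated min-form.

The τ sweep and scan-length curve rerun the full identification per grid
point; sweep results carry metric, seed, and cohort metadata so any point
is independently recomputable. One caution on extreme τ: as τ → ∞,
d_AI(A+τI, B+τI) → ‖A−B‖_F/τ, i.e. the *ordering* degenerates to the
Euclidean one rather than to noise. Very large τ therefore destroys the
geometry but not necessarily the identification, and the package tests
exactly this (the τ = 10⁶ predictions equal the Euclidean ones) rather
than a chance-level collapse.

## The synthetic cohort generator

A linear factor model: population loadings L0 (m × k, standard normal),
subject loadings L_i = L0 + subject_sd·(v ⊙ Δ_i) with Δ_i a fixed
subject-specific perturbation (the fingerprint) and v the per-region
network-variability multiplier; each session is T frames of x_t = L_i f_t +
session_noise_sd·ε_t with fresh factors and noise per session. The knobs
map one-to-one onto the quantities the experiments manipulate:

* `subject_sd` — between-subject signal. 0 gives chance-level
  identification (~1/N); 1.0 is the "strong signal" condition used in the
  robustness and scan-length checks, the top of the monotonicity grid
  {0, 0.1, 0.3, 1.0}.
* `session_noise_sd` — within-subject session noise (default 1.0, i.e.
  noise comparable to signal).
* `n_frames` vs `n_regions` — the rank regime: T ≤ m forces FC rank ≤ T−1.
* `network_variability` — concentrates the fingerprint in chosen networks;
  a 5× network reliably tops the per-network identification profile.

Defaults (N = 40, m = 100, T = 150, k = 10 factors) give a mid-scale,
clearly identifiable cohort that runs in seconds. Seeds are mandatory;
cohorts are bit-reproducible and every experiment record embeds its seed.

What the generator does *not* emulate: temporal autocorrelation of BOLD,
hemodynamics, motion artifacts, global-signal structure, or realistic
anatomical covariance. Passing tests on these cohorts demonstrate the
algebraic and statistical machinery — rank regimes, metric behavior,
calibration — not performance on real fMRI; real-data ID rates depend on
preprocessing and cohort properties outside this package's scope (inputs
are assumed parcellated and minimally preprocessed; global-signal
regression and band-pass filtering are upstream, voxel-level steps and are
deliberately not implemented).

Frame censoring in `clean_timeseries` is list-wise (one shared temporal
mask at |z| > 3 after per-region standardization): pairwise-complete
correlation can produce indefinite matrices, which would break every
SPD-based measure downstream. The region-level analogue of voxel-level
outlier exclusion is genuinely underdetermined; censoring with an exposed
threshold is the conservative choice.

## Problem sizes used in the checked experiments

The scientific checks run at deliberately modest scale, chosen so the full
suite completes in a few minutes while still exhibiting each phenomenon:
metric oracles at dims 1–20; special cases on 50 pairs of dim 8; null-model
calibration at N = 40 with 2000 permutations; rank-regime robustness at
N = 60, m = 120 with T = 80 (rank-deficient) and T = 600 (full-rank);
scan-length monotonicity at N = 40, m = 100 over an 8-point grid from 3 to
120 volumes; the network-contrast experiment at N = 30, m = 42 (seven
6-region networks, one at 5× variability, base subject_sd = 0.15 so that
per-network rates stay below ceiling and the contrast is visible) over ten
seeded replicates. The network-contrast condition was verified to give a
unique top network in 10/10 replicates across four independent seed
decades before being frozen.

## Known limitations

* The Alpha Procrustes evaluation is O(m³) per pair via two
  eigendecompositions; no Cholesky or randomized fast paths.
* The eigenvalue floor interacts with AIRM at τ = 0 on singular operands:
  distances then depend on the floor's magnitude. That regime is for
  probing the failure mode, not for inference — use τ > 0.
* `MetricSpec` validates but ignores parameters irrelevant to the chosen
  measure (e.g. τ for Alpha-Z); misunderstandings are possible if a user
  expects τ to regularize the divergence. The serialized reports always
  echo the full parameter set.
* The permutation null keeps the divergence matrix fixed; it tests label
  exchangeability given the observed distances, not re-sampling variability
  of the distances themselves.
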
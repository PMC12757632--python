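"""Distance and divergence measures between functional connectomes.

Seven measures are provided.  Two operate on the matrix entries directly
(Euclidean, Pearson); five respect the geometry of the SPD cone:

* affine-invariant (AIRM):  d(A,B) = ||log(A^{-1/2} B A^{-1/2})||_F
* Log-Euclidean:            d(A,B) = ||log A - log B||_F
* Bures-Wasserstein:        d(A,B) = sqrt(tr A + tr B - 2 tr (A^{1/2} B A^{1/2})^{1/2})
* Alpha Procrustes:         d(A,B) = (1/a) min_U ||A^a - B^a U||_F over orthogonal U
* Alpha-Z divergence:       Phi(A,B) = tr((1-a)A + aB) - tr Q_{a,z}(A,B),
                            Q_{a,z}(A,B) = (A^{(1-a)/2z} B^{a/z} A^{(1-a)/2z})^z

The Alpha-Z divergence is the centerpiece: it uses only positive fractional
powers, so it is well defined on rank-deficient connectomes where the two
log-based geodesics need ridge regularization (tau) to exist at all.  It is
asymmetric in its arguments for alpha != 1/2; throughout the package the
first argument is the train-session matrix.

The Alpha Procrustes distance is evaluated in closed form: the minimizing
orthogonal U is the polar factor of the classical orthogonal Procrustes
problem, giving min_U ||A^a - B^a U||_F^2 = tr A^{2a} + tr B^{2a}
- 2 tr (A^a B^{2a} A^a)^{1/2}.  The 1/a prefactor normalizes the family so
that its Bures-Wasserstein special case (a = 1/2, factor 2) and its
Log-Euclidean limit (a -> 0) hold with their conventional scales.

Batch evaluation (:func:`pairwise_matrix`) caches the per-matrix spectral
factors (square roots, logs, fractional powers) so each of the n_train x
n_test pairs costs one or two matrix products plus a symmetric eigenvalue
solve instead of a full per-pair decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .linalg import (
    DEFAULT_EIG_FLOOR,
    SingularMatrixError,
    ensure_symmetric,
    matrix_power_psd,
    regularize,
    sym_eig,
)

__all__ = [
    "METRIC_NAMES",
    "MetricSpec",
    "DivergenceMatrix",
    "euclidean_dist",
    "pearson_dist",
    "airm_dist",
    "log_euclidean_dist",
    "bures_wasserstein_dist",
    "alpha_procrustes_dist",
    "alpha_z_divergence",
    "matrix_power_mean",
    "pairwise_matrix",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = (
    "euclidean",
    "pearson",
    "airm",
    "log_euclidean",
    "bures_wasserstein",
    "alpha_procrustes",
    "alpha_z",
)

# CLI-facing aliases -> canonical names
_ALIASES = {
    "bw": "bures_wasserstein",
    "log-euclidean": "log_euclidean",
    "alpha-procrustes": "alpha_procrustes",
    "alpha-z": "alpha_z",
    "affine_invariant": "airm",
    "affine-invariant": "airm",
    "ai": "airm",
}

# fixed tuning choices used throughout: alpha = 0.99, z = 1 for the Alpha-Z
# divergence; alpha = 0.6 for Alpha Procrustes
_DEFAULT_ALPHA = {"alpha_procrustes": 0.6, "alpha_z": 0.99}

# negative values larger than this (times the operand scale) are not rounding
_NEG_TOL = 1e-6

# squared distances computed as differences of traces (Bures-Wasserstein,
# Alpha Procrustes) carry absolute error ~eps * operand trace; below this
# relative threshold they are numerically indistinguishable from zero
_SQ_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class MetricSpec:
    """Which measure to use, plus its parameters.

    Parameters irrelevant to the named measure are validated but ignored:
    ``alpha`` matters to alpha_procrustes (default 0.6) and alpha_z (default
    0.99); ``z`` to alpha_z only (default 1); ``tau`` adds tau*I to both
    operands of the log-based measures airm and log_euclidean; ``eig_floor``
    is the eigenvalue floor those measures fall back on when tau = 0 leaves
    a singular operand.
    """

    name: str
    alpha: float | None = None
    z: float = 1.0
    tau: float = 0.0
    eig_floor: float = DEFAULT_EIG_FLOOR

    def __post_init__(self) -> None:
        canonical = _ALIASES.get(self.name, self.name)
        if canonical not in METRIC_NAMES:
            raise ValueError(
                f"unknown metric {self.name!r}; choose from {', '.join(METRIC_NAMES)}"
            )
        object.__setattr__(self, "name", canonical)
        if self.alpha is None:
            object.__setattr__(self, "alpha", _DEFAULT_ALPHA.get(canonical, 0.5))
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.z > 0:
            raise ValueError(f"z must be > 0, got {self.z}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if self.eig_floor < 0:
            raise ValueError(f"eig_floor must be >= 0, got {self.eig_floor}")

    @property
    def is_symmetric(self) -> bool:
        """True unless the measure depends on argument order (alpha_z, alpha != 1/2)."""
        return not (self.name == "alpha_z" and self.alpha != 0.5)

    def to_dict(self) -> dict:
        return {
            "metric": self.name,
            "alpha": self.alpha,
            "z": self.z,
            "tau": self.tau,
            "eig_floor": self.eig_floor,
        }


@dataclass
class DivergenceMatrix:
    """Cross-session distance table D[i, j] = d(train_i, test_j)."""

    values: np.ndarray
    train_ids: Sequence[str]
    test_ids: Sequence[str]
    spec: MetricSpec = field(default_factory=lambda: MetricSpec("alpha_z"))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("divergence table must be 2-D")
        if self.values.shape != (len(self.train_ids), len(self.test_ids)):
            raise ValueError(
                f"table shape {self.values.shape} does not match "
                f"{len(self.train_ids)} train / {len(self.test_ids)} test ids"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("divergence table contains non-finite entries")


# ---------------------------------------------------------------------------
# spectral helpers

def _eig_psd(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return sym_eig(A)


def _psd_eigvals(C: np.ndarray) -> np.ndarray:
    """Eigenvalues of a symmetric matrix that is PSD up to rounding, clipped >= 0."""
    C = (C + C.T) / 2.0
    w = np.linalg.eigvalsh(C)
    return np.clip(w, 0.0, None)


def _clip_tiny_negative(value: float, scale: float, what: str) -> float:
    """Clip float-rounding negatives to 0; larger negatives are a hard error."""
    if value >= 0.0:
        return value
    if value < -_NEG_TOL * max(scale, 1.0):
        raise FloatingPointError(
            f"{what} produced {value:.3g}, beyond rounding tolerance"
        )
    logger.debug("%s: clipping tiny negative %.3g to 0", what, value)
    return 0.0


def _floored_pd_eig(
    A: np.ndarray, spec: MetricSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Eigensystem of A + tau*I with the spec's eigenvalue floor applied.

    Raises :class:`SingularMatrixError` when the operand stays singular and
    no floor is available — the rank-deficiency failure mode of the
    inversion-based geodesics; the fix is tau > 0.
    """
    w, V = _eig_psd(regularize(A, spec.tau))
    wmin = float(w[-1])
    if wmin <= 0.0:
        if spec.eig_floor > 0.0:
            logger.warning(
                "%s: operand singular at tau=%g; flooring eigenvalues at %.3g",
                spec.name,
                spec.tau,
                spec.eig_floor,
            )
        else:
            raise SingularMatrixError(
                f"{spec.name}: operand is singular after tau={spec.tau} "
                "regularization; use tau > 0 or a positive eig_floor"
            )
    if spec.eig_floor > 0.0:
        w = np.maximum(w, spec.eig_floor)
    return w, V


def _upper_triangle(A: np.ndarray) -> np.ndarray:
    """Strict upper triangle, row-major — the FC edge-weight vectorization."""
    m = A.shape[0]
    iu = np.triu_indices(m, k=1)
    return A[iu]


# ---------------------------------------------------------------------------
# per-metric prepared representations for batch evaluation
#
# _prep(A, spec, side) -> cached factors; _pair(pa, pb, spec) -> the measure.
# side is "train" (first argument) or "test" (second); the cached factors
# differ between sides for the asymmetric divergence and for the measures
# whose closed forms sandwich one operand's power around the other.


def _prep_euclidean(A, spec, side):
    return (ensure_symmetric(A),)


def _pair_euclidean(pa, pb, spec):
    return float(np.linalg.norm(pa[0] - pb[0]))


def _prep_pearson(A, spec, side):
    v = _upper_triangle(ensure_symmetric(A))
    if v.size < 1:
        raise ValueError("pearson distance needs dimension >= 2")
    c = v - v.mean()
    norm = float(np.linalg.norm(c))
    if norm == 0.0:
        raise ValueError(
            "degenerate connectome: off-diagonal entries have zero variance"
        )
    return (c / norm,)


def _pair_pearson(pa, pb, spec):
    r = float(np.dot(pa[0], pb[0]))
    return 1.0 - min(1.0, max(-1.0, r))


def _prep_airm(A, spec, side):
    w, V = _floored_pd_eig(A, spec)
    if side == "train":
        return ((V * w**-0.5) @ V.T,)  # (A + tau I)^{-1/2}
    return ((V * w) @ V.T,)  # A + tau I, floored


def _pair_airm(pa, pb, spec):
    R = pa[0]
    M = R @ pb[0] @ R
    w = _psd_eigvals(M)
    # M is PD when both operands are; floor guards log against rounding zeros
    w = np.maximum(w, np.finfo(float).tiny)
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def _prep_log_euclidean(A, spec, side):
    w, V = _floored_pd_eig(A, spec)
    return ((V * np.log(w)) @ V.T,)


def _pair_log_euclidean(pa, pb, spec):
    return float(np.linalg.norm(pa[0] - pb[0]))


def _prep_bw(A, spec, side):
    w, V = _eig_psd(A)
    tr = float(np.sum(w))
    if side == "train":
        return ((V * np.sqrt(w)) @ V.T, tr)  # A^{1/2}
    return ((A + A.T) / 2.0, tr)


def _pair_bw(pa, pb, spec):
    S, trA = pa
    B, trB = pb
    cross = float(np.sum(np.sqrt(_psd_eigvals(S @ B @ S))))
    scale = trA + trB
    sq = _clip_tiny_negative(trA + trB - 2.0 * cross, scale, "bures_wasserstein")
    if sq < _SQ_ZERO_TOL * max(scale, 1.0):
        sq = 0.0
    return float(np.sqrt(sq))


def _prep_alpha_procrustes(A, spec, side):
    a = spec.alpha
    w, V = _eig_psd(A)
    tr2a = float(np.sum(w ** (2 * a)))
    if side == "train":
        return ((V * w**a) @ V.T, tr2a)  # A^alpha
    return ((V * w ** (2 * a)) @ V.T, tr2a)  # B^{2 alpha}


def _pair_alpha_procrustes(pa, pb, spec):
    Pa, trA = pa
    Qb, trB = pb
    cross = float(np.sum(np.sqrt(_psd_eigvals(Pa @ Qb @ Pa))))
    scale = trA + trB
    sq = _clip_tiny_negative(trA + trB - 2.0 * cross, scale, "alpha_procrustes")
    if sq < _SQ_ZERO_TOL * max(scale, 1.0):
        sq = 0.0
    return float(np.sqrt(sq)) / spec.alpha


def _prep_alpha_z(A, spec, side):
    a, z = spec.alpha, spec.z
    w, V = _eig_psd(A)
    tr = float(np.sum(w))
    if side == "train":
        return ((V * w ** ((1 - a) / (2 * z))) @ V.T, tr)
    return ((V * w ** (a / z)) @ V.T, tr)


def _pair_alpha_z(pa, pb, spec):
    Pa, trA = pa
    Qb, trB = pb
    a, z = spec.alpha, spec.z
    qtrace = float(np.sum(_psd_eigvals(Pa @ Qb @ Pa) ** z))
    phi = (1 - a) * trA + a * trB - qtrace
    return _clip_tiny_negative(phi, trA + trB, "alpha_z")


_IMPL = {
    "euclidean": (_prep_euclidean, _pair_euclidean),
    "pearson": (_prep_pearson, _pair_pearson),
    "airm": (_prep_airm, _pair_airm),
    "log_euclidean": (_prep_log_euclidean, _pair_log_euclidean),
    "bures_wasserstein": (_prep_bw, _pair_bw),
    "alpha_procrustes": (_prep_alpha_procrustes, _pair_alpha_procrustes),
    "alpha_z": (_prep_alpha_z, _pair_alpha_z),
}


def _evaluate(A: np.ndarray, B: np.ndarray, spec: MetricSpec) -> float:
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"dimension mismatch: {A.shape} vs {B.shape}")
    prep, pair = _IMPL[spec.name]
    return pair(prep(A, spec, "train"), prep(B, spec, "test"), spec)


# ---------------------------------------------------------------------------
# public single-pair API


def euclidean_dist(A: np.ndarray, B: np.ndarray) -> float:
    """Frobenius norm of the entrywise difference, ||A - B||_F."""
    return _evaluate(A, B, MetricSpec("euclidean"))


def pearson_dist(A: np.ndarray, B: np.ndarray) -> float:
    """1 - Pearson correlation of the strict-upper-triangle edge vectors.

    The diagonal of a correlation FC is identically 1 and carries no
    information, so it is excluded from the vectorization.  Range [0, 2].
    """
    return _evaluate(A, B, MetricSpec("pearson"))


def airm_dist(A: np.ndarray, B: np.ndarray, spec: MetricSpec | None = None) -> float:
    """Affine-invariant geodesic distance, after tau-regularizing both operands.

    Invariant under congruence d(MAM', MBM') = d(A, B) for invertible M, but
    undefined on singular operands: rank-deficient connectomes need tau > 0.
    """
    spec = replace(spec, name="airm") if spec else MetricSpec("airm")
    return _evaluate(A, B, spec)


def log_euclidean_dist(
    A: np.ndarray, B: np.ndarray, spec: MetricSpec | None = None
) -> float:
    """Log-Euclidean distance ||log(A + tau I) - log(B + tau I)||_F."""
    spec = replace(spec, name="log_euclidean") if spec else MetricSpec("log_euclidean")
    return _evaluate(A, B, spec)


def bures_wasserstein_dist(A: np.ndarray, B: np.ndarray) -> float:
    """Bures-Wasserstein distance (optimal transport between centered Gaussians).

    Needs no inversion, so it is defined for any PSD pair including
    rank-deficient connectomes.  Homogeneous of degree 1/2: d(cA, cB) =
    sqrt(c) d(A, B).
    """
    return _evaluate(A, B, MetricSpec("bures_wasserstein"))


def alpha_procrustes_dist(
    A: np.ndarray, B: np.ndarray, spec: MetricSpec | None = None
) -> float:
    """Alpha Procrustes distance, interpolating Bures-Wasserstein and Log-Euclidean.

    At alpha = 1/2 it equals exactly 2 * bures_wasserstein_dist(A, B); as
    alpha -> 0 it converges to the Log-Euclidean distance.
    """
    spec = (
        replace(spec, name="alpha_procrustes") if spec else MetricSpec("alpha_procrustes")
    )
    return _evaluate(A, B, spec)


def alpha_z_divergence(
    A: np.ndarray, B: np.ndarray, spec: MetricSpec | None = None
) -> float:
    """Alpha-Z Bures-Wasserstein divergence Phi(A, B).

    Phi >= 0 with equality iff A = B; asymmetric in (A, B) for alpha != 1/2.
    Uses only positive fractional powers, hence defined on any PSD pair.
    Special case: alpha = z = 1/2 gives half the squared Bures-Wasserstein
    distance.
    """
    spec = replace(spec, name="alpha_z") if spec else MetricSpec("alpha_z")
    return _evaluate(A, B, spec)


def matrix_power_mean(
    A: np.ndarray, B: np.ndarray, t: float, p: float
) -> np.ndarray:
    """Matrix power (quasi-arithmetic) mean (t A^p + (1-t) B^p)^{1/p}.

    Defined for weights t in [0, 1] and exponents p in [1/2, 1].  The
    Alpha-Z divergence satisfies in-betweenness with respect to this mean:
    Phi(A, mu_p(t; A, B)) <= Phi(A, B).
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t must be in [0, 1], got {t}")
    if not 0.5 <= p <= 1.0:
        raise ValueError(f"p must be in [1/2, 1], got {p}")
    Ap = matrix_power_psd(A, p)
    Bp = matrix_power_psd(B, p)
    return matrix_power_psd(t * Ap + (1 - t) * Bp, 1.0 / p)


def pairwise_matrix(
    train: Sequence[np.ndarray],
    test: Sequence[np.ndarray],
    spec: MetricSpec,
    train_ids: Sequence[str] | None = None,
    test_ids: Sequence[str] | None = None,
) -> DivergenceMatrix:
    """All train x test distances, first argument always the train matrix.

    Per-matrix spectral factors are computed once per side, so the cost is
    O((n_train + n_test) m^3) for the decompositions plus O(n_train n_test)
    cheap pair evaluations.  The train-first argument order is the direction
    convention for the asymmetric Alpha-Z divergence.
    """
    if len(train) == 0 or len(test) == 0:
        raise ValueError("train and test sets must be nonempty")
    dims = {np.asarray(M).shape for M in train} | {np.asarray(M).shape for M in test}
    if len(dims) != 1:
        raise ValueError(f"mixed matrix dimensions: {sorted(dims)}")
    prep, pair = _IMPL[spec.name]
    ptrain = [prep(np.asarray(M, dtype=float), spec, "train") for M in train]
    ptest = [prep(np.asarray(M, dtype=float), spec, "test") for M in test]
    D = np.empty((len(train), len(test)))
    for i, pa in enumerate(ptrain):
        for j, pb in enumerate(ptest):
            D[i, j] = pair(pa, pb, spec)
    if train_ids is None:
        train_ids = [str(i) for i in range(len(train))]
    if test_ids is None:
        test_ids = [str(j) for j in range(len(test))]
    return DivergenceMatrix(D, list(train_ids), list(test_ids), spec)
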
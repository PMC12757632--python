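"""The seven comparison measures: scalar oracles, special cases, metric axioms."""

import itertools

import numpy as np
import pytest
from scipy import stats

from spdfinger.metrics import (
    MetricSpec,
    airm_dist,
    alpha_procrustes_dist,
    alpha_z_divergence,
    bures_wasserstein_dist,
    euclidean_dist,
    log_euclidean_dist,
    matrix_power_mean,
    pairwise_matrix,
    pearson_dist,
)

# ---------------------------------------------------------------------------
# scalar closed forms on diagonal operands (everything commutes)


def _scalar_euclidean(a, b, spec):
    return np.sqrt(np.sum((a - b) ** 2))


def _scalar_airm(a, b, spec):
    return np.sqrt(np.sum(np.log((b + spec.tau) / (a + spec.tau)) ** 2))


def _scalar_bw(a, b, spec):
    return np.sqrt(np.sum(a) + np.sum(b) - 2 * np.sum(np.sqrt(a * b)))


def _scalar_alpha_procrustes(a, b, spec):
    al = spec.alpha
    return (
        np.sqrt(np.sum(a ** (2 * al)) + np.sum(b ** (2 * al)) - 2 * np.sum((a * b) ** al))
        / al
    )


def _scalar_alpha_z(a, b, spec):
    al = spec.alpha
    return np.sum((1 - al) * a + al * b - a ** (1 - al) * b**al)


_DIAGONAL_ORACLES = [
    (lambda A, B, s: euclidean_dist(A, B), _scalar_euclidean, MetricSpec("euclidean")),
    (airm_dist, _scalar_airm, MetricSpec("airm", tau=0.1)),
    (log_euclidean_dist, _scalar_airm, MetricSpec("log_euclidean", tau=0.1)),
    (lambda A, B, s: bures_wasserstein_dist(A, B), _scalar_bw, MetricSpec("bures_wasserstein")),
    (alpha_procrustes_dist, _scalar_alpha_procrustes, MetricSpec("alpha_procrustes", alpha=0.6)),
    (alpha_z_divergence, _scalar_alpha_z, MetricSpec("alpha_z", alpha=0.99, z=1.0)),
]


@pytest.mark.parametrize(
    "matrix_fn,scalar_fn,spec",
    _DIAGONAL_ORACLES,
    ids=[s.name for *_, s in _DIAGONAL_ORACLES],
)
def test_diagonal_operands_match_scalar_closed_form(matrix_fn, scalar_fn, spec, rng):
    """On commuting (diagonal) pairs every measure reduces to its scalar form."""
    for dim in (1, 2, 5, 13, 20):
        a = rng.uniform(0.2, 5.0, size=dim)
        b = rng.uniform(0.2, 5.0, size=dim)
        got = matrix_fn(np.diag(a), np.diag(b), spec)
        want = scalar_fn(a, b, spec)
        assert got == pytest.approx(want, rel=1e-8, abs=1e-12)


def test_pearson_matches_scipy_on_upper_triangles(rng):
    """Pearson distance is 1 - pearsonr of the strict-upper-triangle vectors."""
    for dim in (3, 6, 12):
        A = rng.standard_normal((dim, dim))
        A = (A + A.T) / 2
        B = rng.standard_normal((dim, dim))
        B = (B + B.T) / 2
        iu = np.triu_indices(dim, k=1)
        want = 1 - stats.pearsonr(A[iu], B[iu]).statistic
        assert pearson_dist(A, B) == pytest.approx(want, rel=1e-10)


def test_pearson_perfect_anticorrelation():
    """Reversed upper triangle (0.1,0.2,0.3)->(0.3,0.2,0.1) gives distance 2."""
    A = np.eye(3)
    B = np.eye(3)
    A[0, 1] = A[1, 0] = 0.1
    A[0, 2] = A[2, 0] = 0.2
    A[1, 2] = A[2, 1] = 0.3
    B[0, 1] = B[1, 0] = 0.3
    B[0, 2] = B[2, 0] = 0.2
    B[1, 2] = B[2, 1] = 0.1
    assert pearson_dist(A, B) == pytest.approx(2.0, abs=1e-12)
    assert pearson_dist(A, A) == pytest.approx(0.0, abs=1e-12)


def test_pearson_degenerate_connectome_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        pearson_dist(np.eye(3), np.eye(3))


# ---------------------------------------------------------------------------
# printed examples and special cases


def test_euclidean_examples(make_spd):
    A = make_spd(4)
    assert euclidean_dist(A, A) == 0.0
    assert euclidean_dist(np.eye(2), 2 * np.eye(2)) == pytest.approx(np.sqrt(2))
    assert euclidean_dist(np.diag([3.0, 0.0]), np.diag([0.0, 4.0])) == pytest.approx(5.0)


def test_airm_diagonal_closed_form():
    d = airm_dist(np.eye(2), np.diag([np.e**2, 1.0]), MetricSpec("airm", eig_floor=0.0))
    assert d == pytest.approx(2.0, rel=1e-10)


def test_airm_affine_invariance(make_spd, rng):
    A, B = make_spd(6), make_spd(6)
    M = rng.standard_normal((6, 6)) + 0.5 * np.eye(6)
    spec = MetricSpec("airm", eig_floor=0.0)
    d0 = airm_dist(A, B, spec)
    d1 = airm_dist(M @ A @ M.T, M @ B @ M.T, spec)
    assert d1 == pytest.approx(d0, rel=1e-6)


def test_log_euclidean_equals_airm_on_commuting_pair(rng):
    a = rng.uniform(0.5, 3.0, 5)
    b = rng.uniform(0.5, 3.0, 5)
    spec = MetricSpec("log_euclidean", eig_floor=0.0)
    d_le = log_euclidean_dist(np.diag(a), np.diag(b), spec)
    d_ai = airm_dist(np.diag(a), np.diag(b), MetricSpec("airm", eig_floor=0.0))
    assert d_le == pytest.approx(d_ai, abs=1e-10)


def test_bures_wasserstein_scalar_and_scaling(make_psd):
    assert bures_wasserstein_dist(np.array([[4.0]]), np.array([[1.0]])) == pytest.approx(1.0)
    A, B = make_psd(6, 4), make_psd(6, 6)
    assert bures_wasserstein_dist(4 * A, 4 * B) == pytest.approx(
        2 * bures_wasserstein_dist(A, B), rel=1e-8
    )


def test_alpha_procrustes_half_is_twice_bw(make_spd):
    """At alpha = 1/2 the family reduces to 2 x Bures-Wasserstein."""
    spec = MetricSpec("alpha_procrustes", alpha=0.5)
    assert alpha_procrustes_dist(
        np.array([[4.0]]), np.array([[1.0]]), spec
    ) == pytest.approx(2.0, rel=1e-10)
    for _ in range(10):
        A, B = make_spd(8), make_spd(8)
        assert alpha_procrustes_dist(A, B, spec) == pytest.approx(
            2 * bures_wasserstein_dist(A, B), rel=1e-8
        )


def test_alpha_procrustes_log_euclidean_limit(make_spd):
    """As alpha -> 0 the family converges to the Log-Euclidean distance."""
    spec = MetricSpec("alpha_procrustes", alpha=1e-4)
    d_le = log_euclidean_dist(np.eye(2), np.diag([np.e**2, 1.0]), MetricSpec("log_euclidean", eig_floor=0.0))
    assert d_le == pytest.approx(2.0, rel=1e-10)
    assert alpha_procrustes_dist(np.eye(2), np.diag([np.e**2, 1.0]), spec) == pytest.approx(
        2.0, rel=1e-3
    )
    A, B = make_spd(5), make_spd(5)
    assert alpha_procrustes_dist(A, B, spec) == pytest.approx(
        log_euclidean_dist(A, B, MetricSpec("log_euclidean", eig_floor=0.0)), rel=1e-3
    )


def test_alpha_z_half_half_is_half_squared_bw(make_spd, make_psd):
    spec = MetricSpec("alpha_z", alpha=0.5, z=0.5)
    assert alpha_z_divergence(np.array([[4.0]]), np.array([[1.0]]), spec) == pytest.approx(0.5)
    for A, B in [(make_spd(8), make_spd(8)), (make_psd(8, 3), make_psd(8, 5))]:
        assert alpha_z_divergence(A, B, spec) == pytest.approx(
            0.5 * bures_wasserstein_dist(A, B) ** 2, rel=1e-8
        )


def test_alpha_z_identity_and_defaults(make_spd, make_psd):
    spec = MetricSpec("alpha_z")
    assert spec.alpha == 0.99 and spec.z == 1.0
    for A in (make_spd(6), make_psd(6, 2)):
        assert alpha_z_divergence(A, A, spec) == pytest.approx(0.0, abs=1e-10)
    a = alpha_z_divergence(np.array([[1.0]]), np.array([[4.0]]), spec)
    assert a == pytest.approx(0.01 * 1 + 0.99 * 4 - 4**0.99, rel=1e-10)


def test_alpha_z_is_asymmetric(make_spd):
    spec = MetricSpec("alpha_z", alpha=0.99)
    assert not spec.is_symmetric
    A, B = make_spd(5), make_spd(5)
    assert abs(alpha_z_divergence(A, B, spec) - alpha_z_divergence(B, A, spec)) > 1e-8


# ---------------------------------------------------------------------------
# metric axioms on random SPD ensembles

_SYMMETRIC_SPECS = [
    MetricSpec("euclidean"),
    MetricSpec("pearson"),
    MetricSpec("airm", tau=0.05),
    MetricSpec("log_euclidean", tau=0.05),
    MetricSpec("bures_wasserstein"),
    MetricSpec("alpha_procrustes"),
]

_TRIANGLE_SPECS = [s for s in _SYMMETRIC_SPECS if s.name != "pearson"]


def _dist(spec, A, B):
    return pairwise_matrix([A], [B], spec).values[0, 0]


def test_nonnegativity_and_identity(all_specs, make_spd):
    """d >= 0 always; d ~ 0 iff the operands coincide (50 random pairs)."""
    pairs = [(make_spd(10), make_spd(10)) for _ in range(50)]
    for spec in all_specs:
        for A, B in pairs:
            d = _dist(spec, A, B)
            assert d >= 0
            assert d > 1e-8
        A = pairs[0][0]
        assert _dist(spec, A, A) <= 1e-8


def test_symmetry_of_symmetric_measures(make_spd):
    for spec in _SYMMETRIC_SPECS:
        for _ in range(10):
            A, B = make_spd(8), make_spd(8)
            assert abs(_dist(spec, A, B) - _dist(spec, B, A)) <= 1e-10 * (
                1 + _dist(spec, A, B)
            )


def test_triangle_inequality(make_spd):
    for spec in _TRIANGLE_SPECS:
        for _ in range(50):
            A, B, C = make_spd(6), make_spd(6), make_spd(6)
            dAB = _dist(spec, A, B)
            dAC = _dist(spec, A, C)
            dCB = _dist(spec, C, B)
            assert dAB <= dAC + dCB + 1e-10


def test_orthogonal_conjugation_invariance(all_specs, make_spd, rng):
    """d(UAU', UBU') = d(A, B) for every matrix-geometric measure."""
    A, B = make_spd(8), make_spd(8)
    Q, _ = np.linalg.qr(rng.standard_normal((8, 8)))
    for spec in all_specs:
        if spec.name == "pearson":
            continue  # entrywise vectorization is not rotation-invariant
        d0 = _dist(spec, A, B)
        d1 = _dist(spec, Q @ A @ Q.T, Q @ B @ Q.T)
        assert d1 == pytest.approx(d0, rel=1e-8, abs=1e-8)


# ---------------------------------------------------------------------------
# power mean and in-betweenness


def test_power_mean_endpoints_and_fixed_point(make_spd):
    A, B = make_spd(5), make_spd(5)
    assert np.allclose(matrix_power_mean(A, B, t=1.0, p=0.75), (A + A.T) / 2, atol=1e-8)
    assert np.allclose(
        matrix_power_mean(A, B, t=0.3, p=1.0), 0.3 * A + 0.7 * B, atol=1e-8
    )
    assert np.allclose(matrix_power_mean(A, A, t=0.4, p=0.6), (A + A.T) / 2, atol=1e-8)


def test_power_mean_parameter_validation(make_spd):
    A, B = make_spd(3), make_spd(3)
    with pytest.raises(ValueError):
        matrix_power_mean(A, B, t=1.5, p=0.75)
    with pytest.raises(ValueError):
        matrix_power_mean(A, B, t=0.5, p=0.4)


def test_in_betweenness(make_spd, make_psd):
    """Phi(A, mu_p(t;A,B)) <= Phi(A,B), including rank-deficient A."""
    spec = MetricSpec("alpha_z")
    pairs = [(make_spd(6), make_spd(6)) for _ in range(10)]
    pairs += [(make_psd(6, 3), make_spd(6)) for _ in range(10)]
    for A, B in pairs:
        phi_ab = alpha_z_divergence(A, B, spec)
        for p, t in itertools.product((0.5, 0.75, 1.0), (0.25, 0.5, 0.75)):
            mu = matrix_power_mean(A, B, t=t, p=p)
            assert alpha_z_divergence(A, mu, spec) <= phi_ab + 1e-10


# ---------------------------------------------------------------------------
# batch evaluation


def test_pairwise_singleton_zero():
    A = np.diag([1.0, 2.0])
    D = pairwise_matrix([A], [A], MetricSpec("euclidean"))
    assert D.values.shape == (1, 1)
    assert D.values[0, 0] == 0.0


def test_pairwise_euclidean_1x1_example():
    D = pairwise_matrix(
        [np.array([[1.0]]), np.array([[4.0]])],
        [np.array([[1.0]]), np.array([[4.0]])],
        MetricSpec("euclidean"),
    )
    assert np.allclose(D.values, [[0, 3], [3, 0]])


def test_pairwise_alpha_z_direction_convention():
    """Entry [i, j] is Phi(train_i, test_j): the divergence is order-sensitive."""
    spec = MetricSpec("alpha_z", alpha=0.99, z=1.0)

    def phi(a, b):  # scalar oracle
        return 0.01 * a + 0.99 * b - a**0.01 * b**0.99

    D = pairwise_matrix(
        [np.array([[1.0]]), np.array([[4.0]])],
        [np.array([[4.0]]), np.array([[1.0]])],
        spec,
    )
    assert D.values[0, 0] == pytest.approx(phi(1, 4), rel=1e-10)
    assert D.values[1, 1] == pytest.approx(phi(4, 1), rel=1e-10)
    assert D.values[0, 0] != pytest.approx(D.values[1, 1])


def test_pairwise_matches_single_pair_calls(strong_cohort, all_specs):
    """The cached batch path agrees with the one-pair-at-a-time path."""
    train = [fc.values for fc in strong_cohort.sessions(0)][:4]
    test = [fc.values for fc in strong_cohort.sessions(1)][:4]
    singles = {
        "euclidean": lambda A, B, s: euclidean_dist(A, B),
        "pearson": lambda A, B, s: pearson_dist(A, B),
        "airm": airm_dist,
        "log_euclidean": log_euclidean_dist,
        "bures_wasserstein": lambda A, B, s: bures_wasserstein_dist(A, B),
        "alpha_procrustes": alpha_procrustes_dist,
        "alpha_z": alpha_z_divergence,
    }
    for spec in all_specs:
        D = pairwise_matrix(train, test, spec)
        for i, j in itertools.product(range(4), range(4)):
            assert D.values[i, j] == pytest.approx(
                singles[spec.name](train[i], test[j], spec), rel=1e-9, abs=1e-9
            )


def test_pairwise_rejects_mixed_dimensions():
    with pytest.raises(ValueError, match="dimension"):
        pairwise_matrix([np.eye(2)], [np.eye(3)], MetricSpec("euclidean"))
    with pytest.raises(ValueError, match="nonempty"):
        pairwise_matrix([], [np.eye(2)], MetricSpec("euclidean"))


# ---------------------------------------------------------------------------
# MetricSpec validation


def test_metric_spec_aliases_and_validation():
    assert MetricSpec("bw").name == "bures_wasserstein"
    assert MetricSpec("alpha-z").name == "alpha_z"
    assert MetricSpec("alpha_procrustes").alpha == 0.6
    with pytest.raises(ValueError, match="unknown metric"):
        MetricSpec("nonsense")
    with pytest.raises(ValueError, match="alpha"):
        MetricSpec("alpha_z", alpha=1.5)
    with pytest.raises(ValueError, match="z must"):
        MetricSpec("alpha_z", z=0.0)
    with pytest.raises(ValueError, match="tau"):
        MetricSpec("airm", tau=-1.0)
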
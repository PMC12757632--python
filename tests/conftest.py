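import numpy as np
import pytest

from spdfinger import MetricSpec, SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def make_spd(rng):
    """Factory for well-conditioned random SPD matrices."""

    def _make(dim: int, ridge: float = 0.1) -> np.ndarray:
        G = rng.standard_normal((dim, dim))
        return G @ G.T + ridge * np.eye(dim)

    return _make


@pytest.fixture
def make_psd(rng):
    """Factory for rank-deficient random PSD matrices."""

    def _make(dim: int, rank: int) -> np.ndarray:
        G = rng.standard_normal((dim, rank))
        return G @ G.T

    return _make


@pytest.fixture(scope="session")
def strong_cohort():
    """Small, strongly fingerprinted two-session FC cohort (full rank)."""
    config = SimConfig(
        n_subjects=12, n_regions=30, n_frames=100, subject_sd=1.0, seed=99
    )
    return simulate_cohort(config).to_connectomes()


@pytest.fixture
def all_specs():
    """One MetricSpec per measure, with tau for the log-based geodesics."""
    return [
        MetricSpec("euclidean"),
        MetricSpec("pearson"),
        MetricSpec("airm", tau=0.01),
        MetricSpec("log_euclidean", tau=0.01),
        MetricSpec("bures_wasserstein"),
        MetricSpec("alpha_procrustes"),
        MetricSpec("alpha_z"),
    ]
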
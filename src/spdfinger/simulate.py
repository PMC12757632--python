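"""Synthetic two-session cohorts with a controllable connectome fingerprint.

The generator is a linear factor model.  A population loading matrix L0
(m regions x k latent factors) defines the connectivity structure shared by
everyone; subject i perturbs it as

    L_i = L0 + subject_sd * (v ⊙ Δ_i)

where Δ_i is a subject-specific standard-normal matrix, fixed across that
subject's sessions (the fingerprint), and v scales each region's row by its
network's variability multiplier.  A session is then T frames of

    x_t = L_i f_t + session_noise_sd * ε_t

with fresh standard-normal factors f_t and noise ε_t per session.  The three
knobs map onto the quantities fingerprinting experiments manipulate:
``subject_sd`` is between-subject signal, ``session_noise_sd`` is
within-subject session noise, and ``network_variability`` concentrates the
fingerprint in chosen networks.  Choosing T below m produces rank-deficient
connectomes (rank <= T - 1); T well above m produces full-rank ones.

Everything is driven by one mandatory seed, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .connectome import CANONICAL_NETWORKS, Cohort, NetworkAtlas, RegionTimeSeries

__all__ = ["SimConfig", "simulate_cohort", "simulate_atlas"]


@dataclass
class SimConfig:
    """Cohort-generator settings; defaults give a mid-scale identifiable cohort.

    ``shared_factors=True`` reuses one factor sequence for both sessions of a
    subject — with ``session_noise_sd=0`` the two sessions become identical,
    the degenerate perfect-fingerprint case.
    """

    n_subjects: int = 40
    n_regions: int = 100
    n_frames: int = 150
    n_factors: int = 10
    subject_sd: float = 1.0
    session_noise_sd: float = 1.0
    network_sizes: Sequence[int] | None = None
    network_variability: Sequence[float] | None = None
    shared_factors: bool = False
    seed: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        problems = []
        if self.seed is None:
            problems.append("seed is required (reproducibility is mandatory)")
        if self.n_subjects < 2:
            problems.append(f"n_subjects must be >= 2, got {self.n_subjects}")
        if self.n_regions < 2:
            problems.append(f"n_regions must be >= 2, got {self.n_regions}")
        if self.n_frames < 3:
            problems.append(f"n_frames must be >= 3, got {self.n_frames}")
        if self.n_factors < 1:
            problems.append(f"n_factors must be >= 1, got {self.n_factors}")
        if self.subject_sd < 0:
            problems.append(f"subject_sd must be >= 0, got {self.subject_sd}")
        if self.session_noise_sd < 0:
            problems.append(
                f"session_noise_sd must be >= 0, got {self.session_noise_sd}"
            )
        if self.network_sizes is not None:
            if sum(self.network_sizes) != self.n_regions:
                problems.append(
                    f"network_sizes sum to {sum(self.network_sizes)}, "
                    f"expected n_regions = {self.n_regions}"
                )
            if any(s < 1 for s in self.network_sizes):
                problems.append("every network needs at least one region")
        if self.network_variability is not None:
            if self.network_sizes is None:
                problems.append("network_variability requires network_sizes")
            elif len(self.network_variability) != len(self.network_sizes):
                problems.append(
                    "network_variability and network_sizes lengths differ "
                    f"({len(self.network_variability)} vs {len(self.network_sizes)})"
                )
            elif any(v < 0 for v in self.network_variability):
                problems.append("network_variability multipliers must be >= 0")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))

    def region_variability(self) -> np.ndarray:
        """Per-region multiplier on subject_sd, expanded from the network spec."""
        v = np.ones(self.n_regions)
        if self.network_sizes is not None and self.network_variability is not None:
            start = 0
            for size, mult in zip(self.network_sizes, self.network_variability):
                v[start : start + size] = mult
                start += size
        return v

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_regions": self.n_regions,
            "n_frames": self.n_frames,
            "n_factors": self.n_factors,
            "subject_sd": self.subject_sd,
            "session_noise_sd": self.session_noise_sd,
            "network_sizes": list(self.network_sizes) if self.network_sizes else None,
            "network_variability": (
                list(self.network_variability) if self.network_variability else None
            ),
            "shared_factors": self.shared_factors,
            "seed": self.seed,
        }


def simulate_cohort(config: SimConfig) -> Cohort:
    """Draw a two-session time-series cohort from the factor model."""
    rng = np.random.default_rng(config.seed)
    m, k, T = config.n_regions, config.n_factors, config.n_frames
    L0 = rng.standard_normal((m, k))
    v = config.region_variability()[:, None]
    subjects: dict[str, tuple] = {}
    width = len(str(config.n_subjects - 1))
    for i in range(config.n_subjects):
        delta = rng.standard_normal((m, k))
        Li = L0 + config.subject_sd * v * delta
        shared = rng.standard_normal((T, k)) if config.shared_factors else None
        sid = f"sub-{i:0{width}d}"
        sessions = []
        for ses in ("ses-1", "ses-2"):
            F = shared if shared is not None else rng.standard_normal((T, k))
            noise = rng.standard_normal((T, m))
            X = F @ Li.T + config.session_noise_sd * noise
            sessions.append(RegionTimeSeries(X, subject_id=sid, session_id=ses))
        subjects[sid] = tuple(sessions)
    return Cohort(subjects)


def simulate_atlas(
    m: int,
    network_sizes: Sequence[int],
    network_names: Sequence[str] | None = None,
) -> NetworkAtlas:
    """Deterministic atlas of contiguous network blocks covering 0..m-1.

    Defaults to the seven canonical resting-state network names, cycling
    with a numeric suffix if more blocks are requested than names exist.
    """
    if sum(network_sizes) != m:
        raise ValueError(
            f"network sizes sum to {sum(network_sizes)}, expected {m}"
        )
    if any(s < 1 for s in network_sizes):
        raise ValueError("every network needs at least one region")
    if network_names is None:
        base = list(CANONICAL_NETWORKS)
        network_names = [
            base[i] if i < len(base) else f"{base[i % len(base)]}_{i // len(base) + 1}"
            for i in range(len(network_sizes))
        ]
    if len(network_names) != len(network_sizes):
        raise ValueError("network_names and network_sizes lengths differ")
    labels: list[str] = []
    for name, size in zip(network_names, network_sizes):
        labels.extend([name] * size)
    return NetworkAtlas(labels, networks=tuple(network_names))
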
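"""Experiment battery: regularization sweeps, scan-length curves, permutation
null models, per-network identification profiles, and ranking-stability
statistics with FDR control.

All permutation machinery is explicitly seeded; a result object carries
enough metadata (metric parameters, seed, cohort description) for any point
to be recomputed independently.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import Cohort, NetworkAtlas, network_submatrix, truncate_scan
from .identify import IDResult, id_rate, identify_cohort, nn_predict
from .metrics import MetricSpec, pairwise_matrix

__all__ = [
    "SweepResult",
    "NullModelResult",
    "tau_sweep",
    "scan_length_curve",
    "null_model",
    "network_id_profile",
    "spearman_rho",
    "ranking_stability",
    "bh_fdr",
]

_TAU_METRICS = ("airm", "log_euclidean")

#: enumerate all permutations exactly when a ranking has at most this many items
EXACT_PERM_LIMIT = 8


@dataclass
class SweepResult:
    """One identification run per value of a swept parameter."""

    parameter: str
    values: Sequence[float]
    results: Sequence[IDResult]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.values) != len(self.results):
            raise ValueError("one IDResult per parameter value required")
        diffs = np.diff(np.asarray(self.values, dtype=float))
        if np.any(diffs <= 0):
            raise ValueError(f"{self.parameter} values must be strictly increasing")

    @property
    def rates(self) -> np.ndarray:
        return np.array([r.id_rate for r in self.results])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, r in zip(self.values, self.results):
            row = {self.parameter: v, "id_rate": r.id_rate}
            row.update(r.spec.to_dict())
            row.update(self.metadata)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class NullModelResult:
    """Observed identification rate against a label-permutation null."""

    observed_rate: float
    null_rates: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    spec: MetricSpec | None = None

    def to_dict(self) -> dict:
        d = {
            "observed_rate": self.observed_rate,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "null_rate_mean": float(np.mean(self.null_rates)),
            "null_rate_max": float(np.max(self.null_rates)),
        }
        if self.spec is not None:
            d.update(self.spec.to_dict())
        return d


def tau_sweep(
    cohort: Cohort, base_spec: MetricSpec, taus: Sequence[float]
) -> SweepResult:
    """Identification rate across a grid of ridge-regularization strengths.

    Only the log-based geodesics (airm, log_euclidean) depend on tau; for
    them, tiny tau on rank-deficient connectomes lets near-null eigenvalue
    noise dominate the geodesic, while very large tau swamps the signal with
    tau*I — the sweep exposes both failure modes.
    """
    if base_spec.name not in _TAU_METRICS:
        raise ValueError(
            f"tau sweep applies to {_TAU_METRICS}, not {base_spec.name!r}"
        )
    if len(taus) == 0:
        raise ValueError("tau grid is empty")
    fcs = cohort.to_connectomes()
    results = [identify_cohort(fcs, replace(base_spec, tau=float(t))) for t in taus]
    return SweepResult(
        parameter="tau",
        values=[float(t) for t in taus],
        results=results,
        metadata={"metric": base_spec.name, "n_subjects": cohort.n_subjects},
    )


def scan_length_curve(
    cohort: Cohort, ks: Sequence[int], spec: MetricSpec
) -> SweepResult:
    """Identification rate as a function of retained scan volumes.

    For each k the connectomes are rebuilt from the first k frames of every
    session, so shorter scans carry both fewer samples and (for k <= m) a
    lower-rank FC.
    """
    if cohort.kind != "timeseries":
        raise ValueError("scan_length_curve needs a time-series cohort")
    if len(ks) == 0:
        raise ValueError("scan-length grid is empty")
    t_min = min(ts.n_frames for pair in cohort.subjects.values() for ts in pair)
    if max(ks) > t_min:
        raise ValueError(f"k={max(ks)} exceeds the shortest session ({t_min} frames)")
    results = []
    for k in ks:
        truncated = cohort.map_sessions(lambda ts, k=k: truncate_scan(ts, int(k)))
        results.append(identify_cohort(truncated, spec))
    return SweepResult(
        parameter="k_volumes",
        values=[int(k) for k in ks],
        results=results,
        metadata={"metric": spec.name, "n_subjects": cohort.n_subjects},
    )


def null_model(
    cohort: Cohort, spec: MetricSpec, n_perm: int, seed: int
) -> NullModelResult:
    """Label-permutation null for the identification rate.

    The cross-session divergence matrix is computed once; each permutation
    reassigns the test-session subject labels uniformly at random and the
    rate is recomputed from the same matrix (only the alignment between rows
    and columns changes).  Under the null the expected rate is 1/N.  The
    p-value uses the add-one estimator (1 + #{null >= observed}) /
    (n_perm + 1), so it is never exactly zero.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    fcs = cohort.to_connectomes()
    ids = fcs.subject_ids
    train = [fc.values for fc in fcs.sessions(0)]
    test = [fc.values for fc in fcs.sessions(1)]
    D = pairwise_matrix(train, test, spec, train_ids=ids, test_ids=ids)
    observed = id_rate(D)
    n = observed.n_subjects
    # predictions never change under relabeling; only correctness does
    pred_A = nn_predict(D, "train_as_db")  # per test column: train index
    pred_B = nn_predict(D, "test_as_db")  # per train row: test column index
    rng = np.random.default_rng(seed)
    idx = np.arange(n)
    null_rates = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)  # test column j now carries label perm[j]
        acc_A = float(np.mean(pred_A == perm))
        acc_B = float(np.mean(perm[pred_B] == idx))
        null_rates[b] = 0.5 * (acc_A + acc_B)
    p = (1 + int(np.sum(null_rates >= observed.id_rate))) / (n_perm + 1)
    return NullModelResult(
        observed_rate=observed.id_rate,
        null_rates=null_rates,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        spec=spec,
    )


def network_id_profile(
    cohort: Cohort, atlas: NetworkAtlas, spec: MetricSpec
) -> dict[str, IDResult]:
    """Identification run restricted to each network's principal submatrix.

    Output preserves the atlas's network order; networks with fewer than two
    regions are skipped (a 1x1 correlation submatrix is identically 1 and
    carries no fingerprint).
    """
    fcs = cohort.to_connectomes()
    profile: dict[str, IDResult] = {}
    for network in atlas.networks:
        if len(atlas.regions_of(network)) < 2:
            import logging

            logging.getLogger(__name__).warning(
                "network %r has < 2 regions; skipped", network
            )
            continue
        sub = fcs.map_sessions(lambda fc, n=network: network_submatrix(fc, atlas, n))
        profile[network] = identify_cohort(sub, spec)
    return profile


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on average ranks, ties averaged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman_rho is undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), clipped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down (step-up)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _rho_against_permutations(
    reference: np.ndarray, other: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Observed rho and one-sided (>=) permutation p, permuting ``other``.

    Exact enumeration of all n! permutations when n <= EXACT_PERM_LIMIT
    (p = #{rho_perm >= rho_obs} / n!); Monte Carlo with the add-one
    estimator otherwise.
    """
    n = reference.size
    rho_obs = spearman_rho(reference, other)
    r_ref = stats.rankdata(reference)
    r_oth = stats.rankdata(other)
    c_ref = r_ref - r_ref.mean()
    c_ref /= np.linalg.norm(c_ref)
    c_oth = r_oth - r_oth.mean()
    norm_oth = np.linalg.norm(c_oth)
    if n <= EXACT_PERM_LIMIT:
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = (c_oth[perms] @ c_ref) / norm_oth
        p = float(np.sum(rhos >= rho_obs - 1e-12)) / math.factorial(n)
    else:
        rhos = np.empty(n_perm)
        for b in range(n_perm):
            rhos[b] = np.dot(c_oth[rng.permutation(n)], c_ref) / norm_oth
        p = (1 + int(np.sum(rhos >= rho_obs - 1e-12))) / (n_perm + 1)
    return rho_obs, p


def ranking_stability(
    profiles: Mapping[tuple[str, int], Sequence[float]],
    reference_granularity: int,
    n_perm: int = 5000,
    seed: int = 0,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Stability of per-network identifiability rankings across granularities.

    ``profiles`` maps (condition, granularity) to the per-network rates (one
    fixed network order across all cells).  Each cell's ranking is compared
    by Spearman correlation against the same condition's ranking at
    ``reference_granularity``; significance comes from a one-sided
    permutation null (does the correlation exceed chance?), and BH-FDR is
    applied jointly across the whole condition x granularity grid.
    Returns a tidy frame with columns condition, granularity, rho, p, q,
    significant.
    """
    conditions = sorted({c for c, _ in profiles})
    missing = [
        (c, reference_granularity)
        for c in conditions
        if (c, reference_granularity) not in profiles
    ]
    if missing:
        raise ValueError(f"missing reference cells: {missing}")
    rng = np.random.default_rng(seed)
    rows = []
    for condition, granularity in sorted(profiles):
        reference = np.asarray(profiles[(condition, reference_granularity)], float)
        cell = np.asarray(profiles[(condition, granularity)], float)
        if cell.shape != reference.shape:
            raise ValueError(
                f"cell {(condition, granularity)} has {cell.size} networks, "
                f"reference has {reference.size}"
            )
        rho, p = _rho_against_permutations(reference, cell, n_perm, rng)
        rows.append(
            {"condition": condition, "granularity": granularity, "rho": rho, "p": p}
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha_level
    return out
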
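"""Eigendecomposition primitives for symmetric positive-semidefinite matrices.

Functional connectomes are correlation matrices: symmetric, PSD up to
floating-point rounding, and rank-deficient whenever the number of fMRI
frames T is at most the number of regions m.  Every matrix function used by
the distance measures (fractional powers, logarithms, ridge regularization)
is built here on top of a single validated eigendecomposition, with the
convention 0^p = 0 for p > 0 so that fractional powers never implicitly
invert a singular matrix.
"""

from __future__ import annotations

import logging

import numpy as np

__all__ = [
    "SYM_TOL",
    "PSD_TOL",
    "DEFAULT_EIG_FLOOR",
    "NotSymmetricError",
    "NotPSDError",
    "SingularMatrixError",
    "ensure_symmetric",
    "sym_eig",
    "matrix_power_psd",
    "matrix_log_pd",
    "regularize",
    "effective_rank",
]

logger = logging.getLogger(__name__)

#: max tolerated |A - A.T| before an input is rejected as asymmetric
SYM_TOL = 1e-10
#: eigenvalues below -PSD_TOL * max(lambda_max, 1) reject the input as non-PSD
PSD_TOL = 1e-8
#: default eigenvalue floor used by log-based measures when tau = 0
DEFAULT_EIG_FLOOR = 1e-10


class NotSymmetricError(ValueError):
    """Input matrix is asymmetric beyond tolerance (transposed/garbled file?)."""


class NotPSDError(ValueError):
    """Input matrix has an eigenvalue too negative to be rounding error."""


class SingularMatrixError(ValueError):
    """A positive-definite operation hit a (numerically) singular operand."""


def ensure_symmetric(A: np.ndarray, sym_tol: float = SYM_TOL) -> np.ndarray:
    """Validate and exactly symmetrize a square matrix.

    Asymmetry up to ``sym_tol`` (scaled by the magnitude of the entries,
    floored at 1) is attributed to rounding and removed as (A + A.T)/2;
    anything larger is rejected rather than silently fixed.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise ValueError("matrix contains non-finite entries")
    scale = max(1.0, float(np.abs(A).max(initial=0.0)))
    asym = float(np.abs(A - A.T).max(initial=0.0))
    if asym > sym_tol * scale:
        raise NotSymmetricError(
            f"asymmetric input: max |A[i,j]-A[j,i]| = {asym:.3g} "
            f"exceeds tolerance {sym_tol * scale:.3g}"
        )
    return (A + A.T) / 2.0


def sym_eig(
    A: np.ndarray,
    sym_tol: float = SYM_TOL,
    psd_tol: float = PSD_TOL,
) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a symmetric PSD matrix.

    Returns ``(eigenvalues, eigenvectors)`` with eigenvalues sorted in
    descending order and clipped at zero.  Negative eigenvalues within
    ``-psd_tol * max(lambda_max, 1)`` are treated as rounding noise (a
    finite-sample correlation matrix is PSD only up to rounding); anything
    more negative raises :class:`NotPSDError`.
    """
    A = ensure_symmetric(A, sym_tol=sym_tol)
    w, V = np.linalg.eigh(A)  # ascending
    scale = max(float(w[-1]), 1.0)
    if w[0] < -psd_tol * scale:
        raise NotPSDError(
            f"not PSD: smallest eigenvalue {w[0]:.3g} below "
            f"-{psd_tol:.1g} * {scale:.3g}"
        )
    w = np.clip(w, 0.0, None)
    return w[::-1].copy(), V[:, ::-1].copy()


def _from_eig(w: np.ndarray, V: np.ndarray) -> np.ndarray:
    M = (V * w) @ V.T
    return (M + M.T) / 2.0


def matrix_power_psd(A: np.ndarray, p: float) -> np.ndarray:
    """A**p for symmetric PSD A and p > 0, with the convention 0**p = 0.

    Only positive powers are supported: the rank of A is preserved and no
    implicit inversion can occur, which is exactly what makes the
    Bures-Wasserstein family safe on rank-deficient connectomes.
    """
    if not p > 0:
        raise ValueError(f"power must be > 0, got {p} (negative powers invert)")
    w, V = sym_eig(A)
    return _from_eig(w**p, V)


def matrix_log_pd(A: np.ndarray, eig_floor: float = DEFAULT_EIG_FLOOR) -> np.ndarray:
    """Matrix logarithm of a symmetric positive-definite matrix.

    Eigenvalues below ``eig_floor`` are raised to ``eig_floor`` when it is
    positive (with a warning: this deliberately lets rank-deficient inputs
    through so their failure mode can be probed, but the distortion is
    explicit).  With ``eig_floor = 0`` a singular input is an error.
    """
    if eig_floor < 0:
        raise ValueError("eig_floor must be >= 0")
    w, V = sym_eig(A)
    wmin = float(w[-1])
    if eig_floor == 0.0:
        if wmin <= 0.0:
            raise SingularMatrixError(
                "singular matrix; regularize with tau or set eig_floor"
            )
        wf = w
    else:
        if wmin < eig_floor:
            logger.warning(
                "matrix_log_pd: flooring %d eigenvalue(s) below %.3g",
                int(np.sum(w < eig_floor)),
                eig_floor,
            )
        wf = np.maximum(w, eig_floor)
    return _from_eig(np.log(wf), V)


def regularize(A: np.ndarray, tau: float) -> np.ndarray:
    """Ridge-regularize: A + tau*I, shifting every eigenvalue by exactly tau."""
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    A = ensure_symmetric(A)
    if tau == 0.0:
        return A
    return A + tau * np.eye(A.shape[0])


def effective_rank(A: np.ndarray, rank_tol: float | None = None) -> int:
    """Number of eigenvalues above ``rank_tol``.

    Default tolerance is 1e-8 times the largest eigenvalue.  A connectome
    built from T mean-centered frames over m >= T regions has rank at most
    T - 1, which this exposes.
    """
    w, _ = sym_eig(A)
    if rank_tol is None:
        rank_tol = 1e-8 * float(w[0])
    if not rank_tol > 0:
        # all-zero matrix: every eigenvalue is 0, rank 0 regardless of tol
        rank_tol = np.finfo(float).tiny
    return int(np.sum(w > rank_tol))
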
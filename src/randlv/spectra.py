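"""Spectral analysis of the community matrix S = DA.

Local stability of a Lotka-Volterra equilibrium is governed by the Jacobian
(community matrix) ``S = D A`` with ``D = diag(N*)``: row *i* of ``A`` scaled
by the equilibrium density ``N_i*``.  Its eigenvalues split into a *bulk* —
an elliptical cloud of n-1 values predicted by random matrix theory, centred
near ``-<N_i*>`` — and an *outlier* associated with the eigenvector ``N*``.

Two exact identities hold whenever ``r = e`` (all growth rates +1):

* ``S N* = -N*`` — the equilibrium vector is a right eigenvector of ``S``
  with eigenvalue -1, so -1 is always in the spectrum of a feasible system;
* ``sum_i lambda_i = trace(S) = -sum_i N_i*``, i.e. ``<lambda_i> = <-N_i*>``.

The critical eigenvalue is ``Lambda = max_i Re(lambda_i)``; ``Lambda < 0``
means local stability, and |Lambda| indexes resilience (inverse return time).
For feasible purely mutualistic communities the Perron-Frobenius theorem
pins ``Lambda = -1``.  For weak interactions ``Lambda`` is well approximated
by ``max(-N*_min, -1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .matrix_gen import InteractionMatrix

__all__ = [
    "SpectralSummary",
    "community_matrix",
    "spectrum",
    "lambda_approx",
    "eigen_density_relation",
    "trace_identity_check",
]


def _as_matrix(A) -> np.ndarray:
    if isinstance(A, InteractionMatrix):
        return A.A
    return np.asarray(A, dtype=float)


@dataclass
class SpectralSummary:
    """Eigen-decomposition summary of a community matrix.

    Attributes
    ----------
    eigenvalues : ndarray of complex
        All n eigenvalues, sorted by descending real part.
    Lambda : float
        Maximum real part (the critical eigenvalue).
    outlier : complex or None
        Eigenvalue whose eigenvector is best aligned (maximal cosine
        similarity) with the supplied ``N*``; None when ``N*`` was not given.
    outlier_index : int or None
        Index of the outlier in ``eigenvalues``.
    bulk_center : complex
        Mean of the non-outlier eigenvalues (of all eigenvalues when no
        outlier was identified).
    locally_stable : bool
        True iff ``Lambda < 0``.
    """

    eigenvalues: np.ndarray
    Lambda: float
    outlier: complex | None
    outlier_index: int | None
    bulk_center: complex
    locally_stable: bool


def community_matrix(A, Nstar: np.ndarray) -> np.ndarray:
    """Build ``S = D A`` with ``D = diag(N*)`` (row i of A scaled by N_i*)."""
    A = _as_matrix(A)
    Nstar = np.asarray(Nstar, dtype=float)
    if Nstar.shape != (A.shape[0],):
        raise ParameterError(
            f"Nstar length {Nstar.shape} does not match matrix of shape {A.shape}"
        )
    return Nstar[:, None] * A


def spectrum(S: np.ndarray, Nstar: np.ndarray | None = None) -> SpectralSummary:
    """Full eigen-decomposition of ``S`` with bulk/outlier classification.

    The outlier is identified as the eigenvalue whose (complex) eigenvector
    has maximal cosine similarity with ``N*`` — robust even when the bulk
    overlaps -1 at small P, where nearest-to--1 matching would misfire.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ParameterError(f"S must be square, got shape {S.shape}")
    w, V = np.linalg.eig(S)
    order = np.argsort(-w.real, kind="stable")
    w, V = w[order], V[:, order]
    Lambda = float(w[0].real)

    outlier = outlier_index = None
    if Nstar is not None:
        Nstar = np.asarray(Nstar, dtype=float)
        if Nstar.shape != (S.shape[0],):
            raise ParameterError("Nstar length does not match S")
        cos = np.abs(V.conj().T @ Nstar) / (
            np.linalg.norm(V, axis=0) * np.linalg.norm(Nstar)
        )
        outlier_index = int(np.argmax(cos))
        outlier = complex(w[outlier_index])
        bulk = np.delete(w, outlier_index)
    else:
        bulk = w
    bulk_center = complex(bulk.mean()) if bulk.size else complex("nan")

    return SpectralSummary(
        eigenvalues=w,
        Lambda=Lambda,
        outlier=outlier,
        outlier_index=outlier_index,
        bulk_center=bulk_center,
        locally_stable=Lambda < 0,
    )


def lambda_approx(Nstar: np.ndarray) -> float:
    """Weak-interaction approximation ``Lambda ~ max(-N*_min, -1)``.

    Valid for feasible communities: the bulk tracks ``-N_i*`` while the
    outlier sits at -1, so the least-negative eigenvalue is whichever of
    ``-N*_min`` and -1 is larger.
    """
    Nstar = np.asarray(Nstar, dtype=float)
    if Nstar.size == 0:
        raise ParameterError("Nstar must be non-empty")
    return float(max(-Nstar.min(), -1.0))


def eigen_density_relation(A, Nstar: np.ndarray) -> np.ndarray:
    """Per-species eigenvalue prediction ``-(1 + E(a_ij)) N_i*``.

    ``E(a_ij)`` is the mean of the nonzero off-diagonal entries of ``A``
    (zero when there are none).  Derived for feasible communities with weak,
    low-variability interactions (competition in the original derivation);
    compare against the sorted real parts of the true spectrum.
    """
    A = _as_matrix(A)
    Nstar = np.asarray(Nstar, dtype=float)
    off = A[~np.eye(A.shape[0], dtype=bool)]
    nz = off[off != 0]
    mean_a = float(nz.mean()) if nz.size else 0.0
    return -(1.0 + mean_a) * Nstar


def trace_identity_check(S: np.ndarray, Nstar: np.ndarray) -> float:
    """Residual of the exact trace identity ``<lambda_i> = <-N_i*>``.

    Returns ``|mean(lambda_i) - mean(-N_i*)|``; for any ``S = DA`` built from
    ``Nstar`` (diagonal of A equal to -1) this is zero up to eigensolver
    round-off, regardless of feasibility.
    """
    S = np.asarray(S, dtype=float)
    Nstar = np.asarray(Nstar, dtype=float)
    w = np.linalg.eigvals(S)
    return float(abs(w.mean() - (-Nstar.mean())))
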
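"""Matrix functional calculus and Kronecker algebra.

Every closed-form expression in this package is of the form
``pi @ g(-c * T) @ e`` for an analytic scalar function ``g`` applied to a
square matrix.  This module provides ``g(A)`` for general analytic ``g``
(:func:`mat_fun`), the matrix exponential, principal fractional powers, and
the Kronecker sum used by the multivariate models.

``g(A)`` is defined through the Cauchy-integral functional calculus; the
numerical evaluation uses an eigendecomposition when the eigenvector basis is
well conditioned and falls back to a Schur--Parlett recurrence otherwise.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import scipy.linalg

__all__ = [
    "mat_exp",
    "mat_fun",
    "mat_frac_power",
    "kron_sum",
    "EIG_COND_THRESHOLD",
]

# Above this eigenvector condition number the eigendecomposition route is
# considered unreliable and scipy's Schur-Parlett implementation is used.
EIG_COND_THRESHOLD = 1e8


def _as_square(A) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise ValueError("matrix entries must be finite")
    return A


def mat_exp(A) -> np.ndarray:
    """Matrix exponential ``exp(A)`` of a square matrix."""
    return scipy.linalg.expm(_as_square(A))


def mat_fun(A, g: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    """Evaluate an analytic scalar function at a square matrix.

    Parameters
    ----------
    A : (p, p) array_like
        Square matrix with finite entries.
    g : callable
        Vectorized scalar function accepting a complex ndarray.  It must be
        analytic on a neighbourhood of the spectrum of ``A``.

    Returns
    -------
    (p, p) ndarray
        ``g(A)``.  The result is returned real when its imaginary part is
        negligible (always the case for real analytic ``g`` and real ``A``).
    """
    A = _as_square(A)
    if A.shape[0] == 1:
        return np.atleast_2d(np.asarray(g(A[0, 0].astype(complex))))
    lam, V = np.linalg.eig(A)
    cond = np.linalg.cond(V)
    if np.isfinite(cond) and cond < EIG_COND_THRESHOLD:
        G = (V * g(lam.astype(complex))) @ np.linalg.inv(V)
    else:
        G = scipy.linalg.funm(A, lambda z: g(np.asarray(z, dtype=complex)))
    return _realify(G)


def _realify(G: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    if np.iscomplexobj(G):
        scale = max(1.0, np.abs(G.real).max())
        if np.abs(G.imag).max() <= tol * scale:
            return G.real.copy()
    return G


def mat_frac_power(A, a: float) -> np.ndarray:
    """Principal fractional power ``A**a`` for ``a > 0``.

    Requires the spectrum of ``A`` to avoid the closed negative real axis,
    which holds in particular for ``A = -T`` with ``T`` the sub-intensity
    matrix of an absorbing Markov chain.
    """
    A = _as_square(A)
    if a <= 0:
        raise ValueError("fractional power exponent must be positive")
    lam = np.linalg.eigvals(A)
    scale = max(1.0, np.abs(lam).max())
    on_branch_cut = (lam.real <= 1e-12 * scale) & (
        np.abs(lam.imag) <= 1e-12 * scale
    )
    if np.any(on_branch_cut):
        raise ValueError(
            "eigenvalue on the closed negative real axis; principal "
            "fractional power is not defined"
        )
    return _realify(scipy.linalg.fractional_matrix_power(A, a))


def kron_sum(A, B) -> np.ndarray:
    """Kronecker sum ``A ⊕ B = A ⊗ I_q + I_p ⊗ B``."""
    A = _as_square(A)
    B = _as_square(B)
    return np.kron(A, np.eye(B.shape[0])) + np.kron(np.eye(A.shape[0]), B)
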
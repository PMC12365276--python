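"""QR orthogonalization: Schwarz-Rutishauser production path, classical
Gram-Schmidt reference.

Both factorizations take the columns of ``A`` as the vectors to
orthogonalize and return ``A = Q R`` with orthonormal ``Q`` columns and
upper-triangular ``R`` whose diagonal holds the residual norms (hence
non-negative, making the factors unique for full-rank input).

The Schwarz-Rutishauser variant projects each column against the
*already-normalized* previous vectors one at a time, subtracting each
projection before computing the next inner product; classical Gram-Schmidt
computes every projection from the original column.  The one-at-a-time
recursion is what keeps orthogonality from decaying on ill-conditioned
input, at the same O(m n^2) cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisMatrix
from .errors import RankDeficiencyError

__all__ = [
    "OrthoFactors",
    "classical_gram_schmidt",
    "schwarz_rutishauser",
    "orthonormality_error",
    "orthonormalize_basis",
]

#: A column is declared collapsed when its post-projection norm falls below
#: this fraction of its pre-projection norm.
RANK_TOL = 1e-12


@dataclass(frozen=True)
class OrthoFactors:
    """A (Q, R) pair; ``Q``'s working vectors are orthonormal.

    For the matrix factorizations the working vectors are Q's *columns*;
    :func:`orthonormalize_basis` returns Q with orthonormal *rows* (the
    analysis basis, one row per polynomial order) and says so in its
    docstring.
    """

    Q: np.ndarray
    R: np.ndarray
    source_shape: tuple[int, int]


def _check_collapse(i: int, post_norm: float, pre_norm: float) -> None:
    if post_norm < RANK_TOL * pre_norm or pre_norm == 0.0:
        ratio = post_norm / pre_norm if pre_norm > 0 else 0.0
        raise RankDeficiencyError(i, ratio)


def classical_gram_schmidt(A: np.ndarray) -> OrthoFactors:
    """Classical Gram-Schmidt QR of the columns of ``A``.

    Every projection coefficient is taken against the original column:
    ``q_i = a_i - sum_{j<i} <a_i, q^_j> q^_j``, then normalized.  Kept as
    the reference oracle for the Schwarz-Rutishauser path.
    """
    A = np.asarray(A, dtype=float)
    m, n = A.shape
    Q = np.zeros((m, n))
    R = np.zeros((n, n))
    for i in range(n):
        a = A[:, i]
        r = Q[:, :i].T @ a
        q = a - Q[:, :i] @ r
        nrm = float(np.linalg.norm(q))
        _check_collapse(i, nrm, float(np.linalg.norm(a)))
        R[:i, i] = r
        R[i, i] = nrm
        Q[:, i] = q / nrm
    return OrthoFactors(Q=Q, R=R, source_shape=(m, n))


def schwarz_rutishauser(A: np.ndarray) -> OrthoFactors:
    """Schwarz-Rutishauser QR of the columns of ``A``.

    Column ``i`` starts as ``a_i`` and is updated sequentially against each
    finalized unit vector: ``r = <q_i, q^_j>; q_i <- q_i - r q^_j`` for
    j = 0..i-1, then ``r_ii = ||q_i||`` and ``q^_i = q_i / r_ii``.  The loop
    is scheduled right-looking (each finalized q^_j updates all later
    columns in one vectorized pass), which applies the identical per-column
    update sequence.
    """
    A = np.asarray(A, dtype=float)
    m, n = A.shape
    Q = A.copy()
    R = np.zeros((n, n))
    pre_norms = np.linalg.norm(A, axis=0)
    for j in range(n):
        nrm = float(np.linalg.norm(Q[:, j]))
        _check_collapse(j, nrm, float(pre_norms[j]))
        R[j, j] = nrm
        Q[:, j] /= nrm
        if j + 1 < n:
            r = Q[:, j] @ Q[:, j + 1:]
            R[j, j + 1:] = r
            Q[:, j + 1:] -= np.outer(Q[:, j], r)
    return OrthoFactors(Q=Q, R=R, source_shape=(m, n))


def orthonormality_error(Q: np.ndarray) -> float:
    """Largest absolute entry of Q^T Q - I over the orthonormalized dimension.

    The entrywise max (Chebyshev norm) is the usual orthogonality-loss
    measure: it does not inflate with dimension, so the same tolerance is
    meaningful from toy to desk-scale matrices.
    """
    Q = np.asarray(Q, dtype=float)
    gram = Q.T @ Q
    resid = gram - np.eye(gram.shape[0])
    return float(np.abs(resid).max())


def orthonormalize_basis(basis: BasisMatrix) -> OrthoFactors:
    """Orthonormalize the basis rows with Schwarz-Rutishauser.

    The objects orthogonalized are the ``n_max + 1`` basis functions, each a
    length-N vector; the returned ``Q`` therefore has orthonormal *rows* of
    shape ``(n_max + 1, N)`` — the analysis basis that makes the forward and
    inverse moment transforms mutually inverse at full order.

    The tabulated weighted basis becomes extremely ill-conditioned near
    full order (high-degree rows alias on the uniform grid), which any
    single Gram-Schmidt sweep turns into orthogonality loss of order
    cond(A) * eps.  A second Schwarz-Rutishauser sweep over the computed
    vectors (the classic "twice is enough" re-orthogonalization) restores
    orthonormality to near machine precision, which is what makes the
    forward/inverse transform pair exact at full order.  The returned
    ``R`` is the product of both sweeps' triangular factors, so
    ``Q^T R ~ basis.values^T`` still holds.
    """
    first = schwarz_rutishauser(basis.values.T)
    second = schwarz_rutishauser(first.Q)
    return OrthoFactors(
        Q=second.Q.T,
        R=second.R @ first.R,
        source_shape=basis.values.shape,
    )
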
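"""Forward/inverse fractional Tchebichef moment transforms and the
order-truncated reconstruction pipeline.

Moments are computed against the Schwarz-Rutishauser-orthonormalized basis
``Q`` (orthonormal rows, one per polynomial order): forward analysis is
``FrTM_n = sum_x Q[n, x] s(x)`` and synthesis is
``s^(x) = sum_n FrTM_n Q[n, x]``.  With orthonormal rows these are mutually
inverse at full order (``n_max = N - 1``) and truncation yields the
orthogonal projection onto the leading basis functions, so reconstruction
error is non-increasing in the retained order.

The 2-D transform is separable (square inputs, one shared 1-D basis per
axis): ``M = Q S Q^T`` and ``S = Q^T M Q``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .basis import BasisConfig, build_basis
from .errors import DomainError
from .ortho import OrthoFactors, orthonormalize_basis

__all__ = [
    "Signal1D",
    "MomentSet",
    "MomentMatrix2D",
    "orthonormal_basis",
    "forward_moments_1d",
    "inverse_moments_1d",
    "forward_moments_2d",
    "inverse_moments_2d",
    "reconstruct",
]


@dataclass(frozen=True)
class Signal1D:
    """A finite real sample sequence s(x), x = 0..N-1."""

    samples: np.ndarray
    sample_rate_hz: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float).ravel()
        object.__setattr__(self, "samples", samples)
        if samples.size < 2:
            raise DomainError(f"signals need at least 2 samples, got {samples.size}")
        if not np.all(np.isfinite(samples)):
            raise DomainError("signal contains non-finite samples")
        if self.sample_rate_hz is not None and not self.sample_rate_hz > 0:
            raise DomainError(f"sample_rate_hz must be positive, got {self.sample_rate_hz}")

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class MomentSet:
    """FrTM coefficients of a 1-D signal, ordered by polynomial degree."""

    coefficients: np.ndarray
    alpha: float
    n_max: int
    source_length: int

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coefficients, dtype=float).ravel()
        object.__setattr__(self, "coefficients", coeffs)
        if coeffs.size != self.n_max + 1:
            raise DomainError(
                f"expected {self.n_max + 1} coefficients, got {coeffs.size}"
            )
        if not np.all(np.isfinite(coeffs)):
            raise DomainError("moments contain non-finite values")

    def truncate(self, n_max: int) -> "MomentSet":
        """Keep orders 0..n_max (the orthogonal-projection coefficients)."""
        if not 0 <= n_max <= self.n_max:
            raise DomainError(f"cannot truncate to n_max={n_max} from {self.n_max}")
        return MomentSet(self.coefficients[: n_max + 1], self.alpha, n_max,
                         self.source_length)


@dataclass(frozen=True)
class MomentMatrix2D:
    """Separable 2-D FrTM coefficients of a square input."""

    coefficients: np.ndarray
    alpha: float
    side_length: int

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coeffs)
        if coeffs.ndim != 2 or coeffs.shape[0] != coeffs.shape[1]:
            raise DomainError(f"2-D moments must be square, got shape {coeffs.shape}")
        if not np.all(np.isfinite(coeffs)):
            raise DomainError("moments contain non-finite values")


@lru_cache(maxsize=32)
def _cached_q(alpha: float, n: int, n_max: int, eps: float) -> OrthoFactors:
    factors = orthonormalize_basis(
        build_basis(BasisConfig(alpha=alpha, signal_length=n, max_order=n_max,
                                grid_epsilon=eps))
    )
    factors.Q.flags.writeable = False
    factors.R.flags.writeable = False
    return factors


def orthonormal_basis(config: BasisConfig) -> OrthoFactors:
    """Orthonormal analysis basis for ``config`` (memoized; arrays read-only).

    Basis construction and orthogonalization are pure functions of the
    config, so repeated transforms at the same (alpha, N, n_max) share one
    factorization.
    """
    return _cached_q(config.alpha, config.signal_length, config.max_order,
                     config.grid_epsilon)


def _q_matrix(Q_basis: OrthoFactors) -> np.ndarray:
    return np.asarray(Q_basis.Q, dtype=float)


def forward_moments_1d(signal: Signal1D, Q_basis: OrthoFactors,
                       alpha: float = float("nan")) -> MomentSet:
    """Analysis: FrTM_n = sum_x Q[n, x] s(x)."""
    Q = _q_matrix(Q_basis)
    if Q.shape[1] != len(signal):
        raise DomainError(
            f"signal length {len(signal)} does not match basis length {Q.shape[1]}"
        )
    return MomentSet(Q @ signal.samples, alpha=alpha, n_max=Q.shape[0] - 1,
                     source_length=len(signal))


def inverse_moments_1d(moments: MomentSet, Q_basis: OrthoFactors) -> Signal1D:
    """Synthesis: s^(x) = sum_{n<=n_max} FrTM_n Q[n, x].

    ``moments`` may hold fewer orders than the basis (truncated
    reconstruction); it may not hold more.
    """
    Q = _q_matrix(Q_basis)
    k = moments.coefficients.size
    if k > Q.shape[0]:
        raise DomainError(
            f"{k} coefficients exceed the {Q.shape[0]} basis orders available"
        )
    return Signal1D(Q[:k].T @ moments.coefficients)


def forward_moments_2d(image: np.ndarray, Q_basis: OrthoFactors,
                       alpha: float = float("nan")) -> MomentMatrix2D:
    """Separable analysis of a square matrix: M = Q S Q^T."""
    S = np.asarray(image, dtype=float)
    Q = _q_matrix(Q_basis)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise DomainError(f"2-D input must be square, got shape {S.shape}")
    if S.shape[0] != Q.shape[1]:
        raise DomainError(
            f"image side {S.shape[0]} does not match basis length {Q.shape[1]}"
        )
    return MomentMatrix2D(Q @ S @ Q.T, alpha=alpha, side_length=S.shape[0])


def inverse_moments_2d(moments: MomentMatrix2D, Q_basis: OrthoFactors) -> np.ndarray:
    """Separable synthesis: S = Q^T M Q."""
    Q = _q_matrix(Q_basis)
    M = moments.coefficients
    if M.shape[0] > Q.shape[0]:
        raise DomainError(
            f"{M.shape[0]} moment orders exceed the {Q.shape[0]} basis orders"
        )
    Qk = Q[: M.shape[0]]
    return Qk.T @ M @ Qk


def reconstruct(signal: Signal1D, config: BasisConfig):
    """Full pipeline: basis -> Schwarz-Rutishauser -> analysis -> synthesis.

    Returns ``(reconstruction, report)`` where the report holds the six
    evaluation measures of the reconstruction against the input.
    """
    from .metrics import evaluate

    if config.signal_length != len(signal):
        raise DomainError(
            f"config signal_length {config.signal_length} does not match "
            f"signal length {len(signal)}"
        )
    Q_basis = orthonormal_basis(config)
    moments = forward_moments_1d(signal, Q_basis, alpha=config.alpha)
    recon = inverse_moments_1d(moments, Q_basis)
    recon = Signal1D(recon.samples, sample_rate_hz=signal.sample_rate_hz,
                     label=signal.label)
    return recon, evaluate(signal.samples, recon.samples)
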
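"""Fractional-order Tchebichef polynomial bases on a discrete grid.

The fractional-order Tchebichef polynomial of degree ``n`` and fractional
order ``alpha > 0`` is the shifted Chebyshev polynomial evaluated at a
fractionally warped argument::

    FrT_n^alpha(t) = T_n(1 - 2 t^alpha),          t in (0, 1).

The family is orthogonal under the weight

    w(t) = t^(alpha/2 - 1) / sqrt(1 - t^alpha),

and the *normalized* (weighted) functions used for signal analysis are

    F~rT_n^alpha(t) = sqrt(w(t) / c_n) * FrT_n^alpha(t),

with norm constants ``c_0 = 2`` and ``c_n = 1`` for ``n >= 1``.  This module
tabulates the family on a midpoint grid three ways — an exact-coefficient
closed form (the slow oracle), the plain three-term recurrence, and the
normalized three-term recurrence used by :func:`build_basis` — so the fast
path can always be checked against the analytic one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, SingularityError

__all__ = [
    "BasisConfig",
    "SampleGrid",
    "BasisMatrix",
    "analytic_frt",
    "frt_coefficients",
    "frt_recurrence",
    "weight",
    "sqrt_weight",
    "norm_constants",
    "normalized_initials",
    "normalized_recurrence",
    "build_basis",
]

#: Largest degree for which the closed-form coefficients are evaluated.
#: Beyond this the alternating integer coefficients exceed ~1e35 and the
#: floating-point summation loses all significance.
MAX_ANALYTIC_ORDER = 30


@dataclass(frozen=True)
class BasisConfig:
    """Parameters fixing a tabulated basis.

    Parameters
    ----------
    alpha : float
        Fractional order, strictly positive.
    signal_length : int
        Number of grid points N (equals the signal length).
    max_order : int
        Highest polynomial degree tabulated (``n_max``); the basis has
        ``max_order + 1`` rows.  Defaults to ``signal_length - 1`` via
        :meth:`full_order`.
    grid_epsilon : float
        Endpoint clearance: grid values are clipped to
        ``[grid_epsilon, 1 - grid_epsilon]`` to stay away from the weight
        singularities at 0 and 1.
    """

    alpha: float
    signal_length: int
    max_order: int
    grid_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise DomainError(f"alpha must be positive, got {self.alpha}")
        if self.signal_length < 1:
            raise DomainError(f"signal_length must be >= 1, got {self.signal_length}")
        if not 0 <= self.max_order <= self.signal_length - 1:
            raise DomainError(
                f"max_order must satisfy 0 <= max_order <= N-1 "
                f"(got max_order={self.max_order}, N={self.signal_length})"
            )
        if not 0 < self.grid_epsilon < 0.5:
            raise DomainError(
                f"grid_epsilon must lie in (0, 0.5), got {self.grid_epsilon}"
            )

    @classmethod
    def full_order(cls, alpha: float, signal_length: int, grid_epsilon: float = 1e-6) -> "BasisConfig":
        """Config with ``max_order = N - 1`` (complete, invertible basis)."""
        return cls(alpha=alpha, signal_length=signal_length,
                   max_order=signal_length - 1, grid_epsilon=grid_epsilon)


@dataclass(frozen=True)
class SampleGrid:
    """Strictly increasing sample abscissae t_x in (0, 1), one per signal index."""

    t_values: np.ndarray

    @classmethod
    def midpoint(cls, n: int, grid_epsilon: float = 1e-6) -> "SampleGrid":
        """Midpoint grid t_x = (x + 1/2) / n, clipped to [eps, 1 - eps]."""
        t = (np.arange(n) + 0.5) / n
        return cls(t_values=np.clip(t, grid_epsilon, 1.0 - grid_epsilon))

    def __len__(self) -> int:
        return len(self.t_values)


@dataclass(frozen=True)
class BasisMatrix:
    """Tabulated normalized basis: ``values[n, x] = F~rT_n^alpha(t_x)``."""

    values: np.ndarray
    norm_constants: np.ndarray
    config: BasisConfig
    grid: SampleGrid = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def frt_coefficients(n: int) -> list[int]:
    """Exact integer coefficients beta_{n,k} of FrT_n in powers of t^alpha.

    beta_{n,k} = (-1)^k * n * 2^(2k) * (n+k-1)! / ((n-k)! (2k)!), with the
    degree-0 convention beta_{0,0} = 1 (FrT_0 = 1).  Computed with Python
    big integers, so no factorial overflow occurs below the order cap.
    """
    if n < 0:
        raise DomainError(f"polynomial degree must be non-negative, got {n}")
    if n > MAX_ANALYTIC_ORDER:
        raise DomainError(
            f"closed-form coefficients are limited to n <= {MAX_ANALYTIC_ORDER} "
            f"(got {n}); use the recurrence for higher orders"
        )
    if n == 0:
        return [1]
    return [
        (-1) ** k * n * 4**k * math.factorial(n + k - 1)
        // (math.factorial(n - k) * math.factorial(2 * k))
        for k in range(n + 1)
    ]


def analytic_frt(n: int, alpha: float, t) -> float | np.ndarray:
    """Closed-form FrT_n^alpha(t) = sum_k beta_{n,k} t^(alpha k).

    The slow, exact-coefficient oracle used to validate the recurrences.
    ``t`` may be a scalar or an array, each entry strictly inside (0, 1).
    """
    if not alpha > 0:
        raise DomainError(f"alpha must be positive, got {alpha}")
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0.0) or np.any(t >= 1.0):
        raise DomainError("t must lie strictly inside (0, 1)")
    beta = frt_coefficients(n)
    y = t**alpha
    # Horner in y = t^alpha
    acc = np.full_like(y, float(beta[-1]))
    for b in reversed(beta[:-1]):
        acc = acc * y + float(b)
    return acc if acc.ndim else float(acc)


def frt_recurrence(n_max: int, alpha: float, grid: SampleGrid) -> np.ndarray:
    """Unweighted values via the three-term recurrence.

    Row 0 is all ones, row 1 is ``1 - 2 t^alpha``, and
    ``row_{n+1} = (2 - 4 t^alpha) row_n - row_{n-1}``.
    Returns an ``(n_max + 1, N)`` matrix.
    """
    if n_max < 0:
        raise DomainError(f"n_max must be non-negative, got {n_max}")
    if not alpha > 0:
        raise DomainError(f"alpha must be positive, got {alpha}")
    ta = grid.t_values**alpha
    out = np.empty((n_max + 1, len(grid)))
    out[0] = 1.0
    if n_max >= 1:
        out[1] = 1.0 - 2.0 * ta
    two_minus_4ta = 2.0 - 4.0 * ta
    for n in range(1, n_max):
        out[n + 1] = two_minus_4ta * out[n] - out[n - 1]
    return out


def weight(t, alpha: float):
    """Orthogonality weight w(t) = t^(alpha/2 - 1) / sqrt(1 - t^alpha)."""
    if not alpha > 0:
        raise DomainError(f"alpha must be positive, got {alpha}")
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0.0):
        raise DomainError("weight is undefined for t <= 0")
    if np.any(t >= 1.0):
        raise SingularityError("weight diverges at t >= 1 (denominator vanishes)")
    w = t ** (alpha / 2.0 - 1.0) / np.sqrt(1.0 - t**alpha)
    return w if w.ndim else float(w)


def sqrt_weight(t, alpha: float):
    """sqrt(w(t)) = t^(alpha/4 - 1/2) * (1 - t^alpha)^(-1/4), evaluated directly."""
    if not alpha > 0:
        raise DomainError(f"alpha must be positive, got {alpha}")
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0.0):
        raise DomainError("sqrt-weight is undefined for t <= 0")
    if np.any(t >= 1.0):
        raise SingularityError("sqrt-weight diverges at t >= 1")
    sw = t ** (alpha / 4.0 - 0.5) * (1.0 - t**alpha) ** -0.25
    return sw if sw.ndim else float(sw)


def norm_constants(n_max: int) -> np.ndarray:
    """c_0 = 2 and c_n = 1 for n >= 1."""
    c = np.ones(n_max + 1)
    c[0] = 2.0
    return c


def normalized_initials(grid: SampleGrid, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """The two seed rows of the normalized recurrence.

    F~rT_0 = sqrt(w(t)) / sqrt(2)   (c_0 = 2)
    F~rT_1 = sqrt(w(t)) * (1 - 2 t^alpha)   (c_1 = 1)
    """
    sw = sqrt_weight(grid.t_values, alpha)
    row0 = sw / math.sqrt(2.0)
    row1 = sw * (1.0 - 2.0 * grid.t_values**alpha)
    return row0, row1


def normalized_recurrence(basis_so_far: np.ndarray, n: int, grid: SampleGrid,
                          alpha: float) -> np.ndarray:
    """Next normalized row from rows 0..n.

    F~rT_{n+1} = (2 - 4 t^alpha) F~rT_n - sqrt(c_{n-1}) F~rT_{n-1},
    where the c_0 = 2 norm constant puts a sqrt(2) on the n = 1 step only.
    """
    if n < 1:
        raise DomainError("normalized recurrence needs rows 0 and 1 (n >= 1)")
    if basis_so_far.shape[0] < n + 1:
        raise DomainError(
            f"rows 0..{n} required, only {basis_so_far.shape[0]} supplied"
        )
    ta = grid.t_values**alpha
    c_prev = 2.0 if n == 1 else 1.0
    return (2.0 - 4.0 * ta) * basis_so_far[n] - math.sqrt(c_prev) * basis_so_far[n - 1]


def build_basis(config: BasisConfig) -> BasisMatrix:
    """Tabulate the normalized basis on the midpoint grid.

    Deterministic in ``config``; rows are generated by the normalized
    three-term recurrence seeded by :func:`normalized_initials`.
    """
    grid = SampleGrid.midpoint(config.signal_length, config.grid_epsilon)
    n_max = config.max_order
    values = np.empty((n_max + 1, config.signal_length))
    row0, row1 = normalized_initials(grid, config.alpha)
    values[0] = row0
    if n_max >= 1:
        values[1] = row1
    for n in range(1, n_max):
        values[n + 1] = normalized_recurrence(values, n, grid, config.alpha)
    return BasisMatrix(
        values=values,
        norm_constants=norm_constants(n_max),
        config=config,
        grid=grid,
    )
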
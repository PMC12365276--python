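"""Evaluation measures for reconstructed / watermarked signals.

MSE, PSNR, KLD, JSD, BER and PRD.  PSNR is referenced to the signal's own
peak amplitude, not a fixed dynamic range.  The divergences compare
amplitude *distributions*: both signals are histogrammed over their shared
amplitude range (64 bins by default), smoothed by a tiny epsilon and
renormalized, and the divergences are reported in nats (natural log), so
the Jensen-Shannon divergence is bounded by ln 2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "MetricReport",
    "mse",
    "psnr",
    "to_distribution",
    "pair_distributions",
    "kld",
    "jsd",
    "ber",
    "prd",
    "evaluate",
]

DEFAULT_BINS = 64
DEFAULT_EPSILON = 1e-12


@dataclass(frozen=True)
class MetricReport:
    """The six measures; ``psnr_db`` is ``math.inf`` for a perfect match."""

    mse: float
    psnr_db: float
    kld_nats: float
    jsd_nats: float
    prd_percent: float
    ber: float | None = None

    def to_dict(self) -> dict:
        d = {
            "mse": self.mse,
            "psnr_db": "inf" if math.isinf(self.psnr_db) else self.psnr_db,
            "kld_nats": self.kld_nats,
            "jsd_nats": self.jsd_nats,
            "prd_percent": self.prd_percent,
        }
        if self.ber is not None:
            d["ber"] = self.ber
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _pair(s, s_hat) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(s, dtype=float).ravel()
    s_hat = np.asarray(s_hat, dtype=float).ravel()
    if s.size != s_hat.size:
        raise DomainError(f"length mismatch: {s.size} vs {s_hat.size}")
    return s, s_hat


def mse(s, s_hat) -> float:
    """Mean squared error (1/N) sum (s - s^)^2."""
    s, s_hat = _pair(s, s_hat)
    return float(np.mean((s - s_hat) ** 2))


def psnr(s, s_hat) -> float:
    """Peak signal-to-noise ratio 20 log10(max|s| / sqrt(MSE)), in dB.

    Returns ``math.inf`` for a bit-exact match; raises for an all-zero
    reference, whose peak is undefined.
    """
    s, s_hat = _pair(s, s_hat)
    peak = float(np.max(np.abs(s)))
    if peak == 0.0:
        raise DomainError("PSNR undefined: reference signal is identically zero")
    err = mse(s, s_hat)
    if err == 0.0:
        return math.inf
    return 20.0 * math.log10(peak / math.sqrt(err))


def to_distribution(s, n_bins: int = DEFAULT_BINS, epsilon: float = DEFAULT_EPSILON,
                    value_range: tuple[float, float] | None = None) -> np.ndarray:
    """Amplitude histogram of ``s`` as a smoothed probability vector.

    ``value_range`` fixes the bin edges; pass the shared range of a signal
    pair (see :func:`pair_distributions`) so both histograms use identical
    bins.  Every bin receives ``epsilon`` mass before renormalization so
    the divergences stay finite.
    """
    s = np.asarray(s, dtype=float).ravel()
    if value_range is None:
        lo, hi = float(np.min(s)), float(np.max(s))
    else:
        lo, hi = value_range
    if hi <= lo:  # constant signal: all mass in one bin
        hi = lo + 1.0
    counts, _ = np.histogram(s, bins=n_bins, range=(lo, hi))
    p = counts.astype(float) + epsilon
    return p / p.sum()


def pair_distributions(s, s_hat, n_bins: int = DEFAULT_BINS,
                       epsilon: float = DEFAULT_EPSILON) -> tuple[np.ndarray, np.ndarray]:
    """Histogram both signals over the union of their amplitude ranges."""
    s, s_hat = _pair(s, s_hat)
    lo = float(min(np.min(s), np.min(s_hat)))
    hi = float(max(np.max(s), np.max(s_hat)))
    rng = (lo, hi)
    return (to_distribution(s, n_bins, epsilon, rng),
            to_distribution(s_hat, n_bins, epsilon, rng))


def kld(p, q) -> float:
    """Kullback-Leibler divergence sum p ln(p/q), in nats."""
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    if p.size != q.size:
        raise DomainError(f"length mismatch: {p.size} vs {q.size}")
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def jsd(p, q) -> float:
    """Jensen-Shannon divergence (1/2) KLD(p||m) + (1/2) KLD(q||m), m = (p+q)/2."""
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    m = 0.5 * (p + q)
    return 0.5 * kld(p, m) + 0.5 * kld(q, m)


def ber(bits_i, bits_j) -> float:
    """Bit error rate: fraction of positions where the sequences differ.

    Accepts 1-D bit sequences or binary matrices of equal shape.
    """
    a = np.asarray(bits_i)
    b = np.asarray(bits_j)
    if a.shape != b.shape:
        raise DomainError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise DomainError("BER undefined for empty sequences")
    return float(np.mean(np.asarray(a, dtype=int) ^ np.asarray(b, dtype=int)))


def prd(i, j) -> float:
    """Percentage root-mean-square difference 100 sqrt(sum(I-J)^2 / sum I^2)."""
    i, j = _pair(i, j)
    denom = float(np.sum(i**2))
    if denom == 0.0:
        raise DomainError("PRD undefined: reference signal is identically zero")
    return 100.0 * math.sqrt(float(np.sum((i - j) ** 2)) / denom)


def evaluate(s, s_hat, n_bins: int = DEFAULT_BINS, epsilon: float = DEFAULT_EPSILON,
             bits_ref=None, bits_test=None) -> MetricReport:
    """All measures of ``s_hat`` against the reference ``s`` in one report."""
    p, q = pair_distributions(s, s_hat, n_bins, epsilon)
    return MetricReport(
        mse=mse(s, s_hat),
        psnr_db=psnr(s, s_hat),
        kld_nats=kld(p, q),
        jsd_nats=jsd(p, q),
        prd_percent=prd(s, s_hat),
        ber=None if bits_ref is None else ber(bits_ref, bits_test),
    )
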
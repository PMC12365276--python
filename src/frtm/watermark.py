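"""Blind moment-domain watermarking of 1-D biosignals.

The signal is mapped to a square matrix (row-major reshape with zero
padding, or a Gramian angular summation field), transformed into the
fractional Tchebichef moment domain, and payload bits are embedded by
quantization index modulation (QIM): a coefficient carrying bit ``b`` is
snapped to the nearest point of one of two interleaved lattices,

    c' = D * round(c / D - b/2) + D * b/2,

so the even lattice carries 0 and the half-offset lattice carries 1.
Extraction is blind: recompute the moments of the watermarked signal and
read each host coefficient's bit as the nearer lattice, then majority-vote
the repetition code.  Host coefficients are visited in deterministic
zigzag order over the anti-diagonals ``n_lo <= i + j <= n_hi`` (DC
excluded); an optional key shuffles the bit-to-coefficient assignment.

With the reshape mapping the 2-D <-> 1-D cycle is lossless on the retained
samples, so the clean-channel round trip is exact.  For padded (non-square)
lengths the quantization perturbs the padding region, which truncation then
discards; embed therefore runs a short re-quantization refinement
(truncate -> re-transform -> re-snap) until the retained samples are
self-consistent.  The angular-field mapping inverts through its diagonal
only and discards off-diagonal watermark energy; extraction under it is
best-effort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .basis import BasisConfig
from .errors import CapacityError, DegenerateNormalizationError, DomainError
from .transform import (Signal1D, forward_moments_2d, inverse_moments_2d,
                        orthonormal_basis)

__all__ = [
    "WatermarkPayload",
    "EmbedConfig",
    "GridImage2D",
    "to_2d",
    "from_2d",
    "capacity",
    "effective_capacity",
    "zigzag_band_indices",
    "fec_encode",
    "fec_decode",
    "embed",
    "extract",
]

#: Default quantization step as a fraction of the largest in-band coefficient.
DEFAULT_DELTA_FRACTION = 0.01

#: Iteration cap for the padded-length re-quantization refinement.
_REFINE_MAX_ITER = 200


@dataclass(frozen=True)
class WatermarkPayload:
    """An opaque binary payload."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=int).ravel()
        object.__setattr__(self, "bits", bits)
        if bits.size < 1:
            raise DomainError("payload must hold at least one bit")
        if not np.all((bits == 0) | (bits == 1)):
            raise DomainError("payload entries must be 0 or 1")

    @classmethod
    def from_string(cls, text: str) -> "WatermarkPayload":
        """Parse an ASCII '0'/'1' string (whitespace ignored)."""
        chars = [c for c in text if not c.isspace()]
        if any(c not in "01" for c in chars):
            raise DomainError("payload string may contain only '0', '1' and whitespace")
        return cls(np.array([int(c) for c in chars]))

    def to_string(self) -> str:
        return "".join(str(b) for b in self.bits)

    def __len__(self) -> int:
        return self.bits.size


@dataclass
class EmbedConfig:
    """Everything the embedder and the blind extractor must share.

    ``alpha_moment`` is the fractional order of the transform;
    ``strength_alpha`` is the capacity/spacing parameter of the capacity
    law C = floor(N / alpha) — the two reuse one symbol in the field but
    are distinct knobs.  ``delta`` is the QIM step; if ``None`` it is set
    at embed time to ``0.01 x max|in-band coefficient|`` and recorded here
    for the extractor.
    """

    alpha_moment: float = 1.0
    strength_alpha: float = 8.0
    delta: float | None = None
    band: tuple[int, int] = (1, 8)
    mapping: str = "reshape"
    fec_repetition: int = 3
    seed: int = 0
    keyed: bool = False
    grid_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if not self.alpha_moment > 0:
            raise DomainError("alpha_moment must be positive")
        if not self.strength_alpha > 0:
            raise DomainError("strength_alpha must be positive")
        if self.delta is not None and not self.delta > 0:
            raise DomainError("delta must be positive")
        n_lo, n_hi = self.band
        if not 1 <= n_lo <= n_hi:
            raise DomainError(f"band must satisfy 1 <= n_lo <= n_hi, got {self.band}")
        if self.mapping not in ("reshape", "gasf"):
            raise DomainError(f"mapping must be 'reshape' or 'gasf', got {self.mapping!r}")
        if self.fec_repetition < 1 or self.fec_repetition % 2 == 0:
            raise DomainError("fec_repetition must be an odd positive integer")

    def to_dict(self) -> dict:
        return {
            "alpha_moment": self.alpha_moment,
            "strength_alpha": self.strength_alpha,
            "delta": self.delta,
            "band": list(self.band),
            "mapping": self.mapping,
            "fec_repetition": self.fec_repetition,
            "seed": self.seed,
            "keyed": self.keyed,
            "grid_epsilon": self.grid_epsilon,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EmbedConfig":
        d = dict(d)
        d["band"] = tuple(d["band"])
        return cls(**d)


@dataclass(frozen=True)
class GridImage2D:
    """A square 2-D representation of a 1-D signal plus inversion metadata."""

    matrix: np.ndarray
    original_length: int
    mapping: str
    norm_min: float = 0.0
    norm_max: float = 1.0

    @property
    def side(self) -> int:
        return self.matrix.shape[0]


def to_2d(signal: Signal1D, mapping: str = "reshape") -> GridImage2D:
    """Map a 1-D signal to a square matrix.

    ``reshape``: row-major fill of the smallest square holding N samples,
    zero-padded; exactly invertible by truncation.  ``gasf``: min-max
    normalize to [0, 1], take phi = arccos(s~) and form
    G[i, j] = cos(phi_i + phi_j) (an N x N Gramian angular summation
    field); invertible through its diagonal.
    """
    s = signal.samples
    n = s.size
    if mapping == "reshape":
        side = int(np.ceil(np.sqrt(n)))
        padded = np.zeros(side * side)
        padded[:n] = s
        return GridImage2D(matrix=padded.reshape(side, side), original_length=n,
                           mapping="reshape")
    if mapping == "gasf":
        lo, hi = float(np.min(s)), float(np.max(s))
        if hi == lo:
            raise DegenerateNormalizationError(
                "constant signal cannot be min-max normalized for the angular field"
            )
        s_norm = (s - lo) / (hi - lo)
        phi = np.arccos(np.clip(s_norm, 0.0, 1.0))
        G = np.cos(phi[:, None] + phi[None, :])
        return GridImage2D(matrix=G, original_length=n, mapping="gasf",
                           norm_min=lo, norm_max=hi)
    raise DomainError(f"unknown mapping {mapping!r}")


def from_2d(image: GridImage2D) -> Signal1D:
    """Invert :func:`to_2d`.

    Reshape: flatten row-major and drop the padding.  Angular field: the
    diagonal holds cos(2 phi) = 2 cos^2(phi) - 1, so
    s~ = sqrt((G_xx + 1) / 2), de-normalized with the stored min/max.
    """
    if image.mapping == "reshape":
        return Signal1D(image.matrix.ravel()[: image.original_length])
    if image.mapping == "gasf":
        diag = np.clip(np.diagonal(image.matrix), -1.0, 1.0)
        s_norm = np.sqrt((diag + 1.0) / 2.0)
        return Signal1D(image.norm_min + s_norm * (image.norm_max - image.norm_min))
    raise DomainError(f"unknown mapping {image.mapping!r}")


def capacity(n_samples: int, strength_alpha: float) -> int:
    """Raw embedding capacity C = floor(N / alpha) bits."""
    if not strength_alpha > 0:
        raise DomainError("strength_alpha must be positive")
    return int(np.floor(n_samples / strength_alpha))


def zigzag_band_indices(side: int, n_lo: int, n_hi: int) -> list[tuple[int, int]]:
    """Coefficient positions with ``n_lo <= i + j <= n_hi``, zigzag order.

    Anti-diagonals are visited in increasing total order i + j, alternating
    traversal direction; (0, 0) is never a host.
    """
    n_hi = min(n_hi, 2 * (side - 1))
    hosts: list[tuple[int, int]] = []
    for d in range(max(n_lo, 1), n_hi + 1):
        i_vals = range(max(0, d - side + 1), min(d, side - 1) + 1)
        diag = [(i, d - i) for i in i_vals]
        if d % 2 == 1:
            diag.reverse()
        hosts.extend(diag)
    return hosts


def effective_capacity(cfg: EmbedConfig, n_samples: int) -> int:
    """Payload bits a config can carry: min(floor(N/alpha), band size) // r."""
    side = n_samples if cfg.mapping == "gasf" else int(np.ceil(np.sqrt(n_samples)))
    n_hosts = len(zigzag_band_indices(side, *cfg.band))
    return min(capacity(n_samples, cfg.strength_alpha), n_hosts) // cfg.fec_repetition


def fec_encode(bits, repetition: int) -> np.ndarray:
    """Repeat each bit ``repetition`` times (repetition code)."""
    if repetition < 1 or repetition % 2 == 0:
        raise DomainError("repetition must be an odd positive integer")
    return np.repeat(np.asarray(bits, dtype=int).ravel(), repetition)


def fec_decode(bits, repetition: int) -> np.ndarray:
    """Majority-vote each block of ``repetition`` bits."""
    if repetition < 1 or repetition % 2 == 0:
        raise DomainError("repetition must be an odd positive integer")
    bits = np.asarray(bits, dtype=int).ravel()
    if bits.size % repetition != 0:
        raise DomainError(
            f"coded length {bits.size} is not a multiple of repetition {repetition}"
        )
    blocks = bits.reshape(-1, repetition)
    return (blocks.sum(axis=1) * 2 > repetition).astype(int)


def _qim_quantize(c: np.ndarray, bits: np.ndarray, delta: float) -> np.ndarray:
    """Snap each coefficient to the lattice of its bit."""
    return delta * np.round(c / delta - bits / 2.0) + delta * bits / 2.0


def _qim_detect(c: np.ndarray, delta: float) -> np.ndarray:
    """Nearer-lattice decision: 0 for the integer lattice, 1 for half-offset."""
    d0 = np.abs(c - delta * np.round(c / delta))
    c1 = delta * (np.round(c / delta - 0.5) + 0.5)
    d1 = np.abs(c - c1)
    return (d1 < d0).astype(int)


def _basis_for(cfg: EmbedConfig, side: int):
    return orthonormal_basis(
        BasisConfig.full_order(cfg.alpha_moment, side, cfg.grid_epsilon)
    )


def _host_order(cfg: EmbedConfig, side: int, n_slots: int) -> list[tuple[int, int]]:
    hosts = zigzag_band_indices(side, *cfg.band)[:n_slots]
    if cfg.keyed:
        perm = np.random.default_rng(cfg.seed).permutation(len(hosts))
        hosts = [hosts[k] for k in perm]
    return hosts


def embed(signal: Signal1D, payload: WatermarkPayload, cfg: EmbedConfig) -> Signal1D:
    """Embed a payload, returning the watermarked signal (same length).

    If ``cfg.delta`` is None the default step (0.01 x the largest in-band
    coefficient magnitude) is computed here and written back into ``cfg``
    so the same object can drive blind extraction.
    """
    n = len(signal)
    cap = effective_capacity(cfg, n)
    if len(payload) > cap:
        raise CapacityError(
            f"payload of {len(payload)} bits exceeds the effective capacity "
            f"{cap} (C = floor(N/alpha) = {capacity(n, cfg.strength_alpha)}, "
            f"repetition {cfg.fec_repetition})"
        )
    image = to_2d(signal, cfg.mapping)
    Q = _basis_for(cfg, image.side)
    M = forward_moments_2d(image.matrix, Q, alpha=cfg.alpha_moment).coefficients.copy()

    coded = fec_encode(payload.bits, cfg.fec_repetition)
    hosts = _host_order(cfg, image.side, coded.size)
    rows = np.array([h[0] for h in hosts])
    cols = np.array([h[1] for h in hosts])

    if cfg.delta is None:
        all_band = zigzag_band_indices(image.side, *cfg.band)
        band_mag = np.abs(M[[h[0] for h in all_band], [h[1] for h in all_band]])
        peak = float(band_mag.max())
        if peak == 0.0:
            raise DomainError("all in-band coefficients are zero; set delta explicitly")
        cfg.delta = DEFAULT_DELTA_FRACTION * peak
    delta = cfg.delta

    M[rows, cols] = _qim_quantize(M[rows, cols], coded, delta)
    wm_matrix = inverse_moments_2d(
        _moment_matrix(M, cfg, image.side), Q
    )

    if cfg.mapping == "reshape" and image.side**2 != n:
        # Truncation discards the watermark energy that leaked into the
        # padding; alternate truncate -> re-transform -> re-snap until the
        # retained samples are a fixed point of the extraction pipeline.
        for _ in range(_REFINE_MAX_ITER):
            trunc = wm_matrix.ravel().copy()
            trunc[n:] = 0.0
            M2 = forward_moments_2d(trunc.reshape(image.side, image.side), Q,
                                    alpha=cfg.alpha_moment).coefficients.copy()
            if np.array_equal(_qim_detect(M2[rows, cols], delta), coded) and np.all(
                np.abs(M2[rows, cols] - M[rows, cols]) < delta * 1e-6
            ):
                wm_matrix = trunc.reshape(image.side, image.side)
                break
            M2[rows, cols] = _qim_quantize(M2[rows, cols], coded, delta)
            M = M2
            wm_matrix = inverse_moments_2d(_moment_matrix(M, cfg, image.side), Q)
        else:
            raise DomainError(
                "watermark refinement did not converge; use a square-length "
                "signal or a larger delta"
            )

    wm_image = replace(image, matrix=wm_matrix)
    out = from_2d(wm_image)
    return Signal1D(out.samples, sample_rate_hz=signal.sample_rate_hz,
                    label=signal.label)


def _moment_matrix(values: np.ndarray, cfg: EmbedConfig, side: int):
    from .transform import MomentMatrix2D

    return MomentMatrix2D(values, alpha=cfg.alpha_moment, side_length=side)


def extract(watermarked: Signal1D, cfg: EmbedConfig,
            payload_length: int) -> WatermarkPayload:
    """Blindly recover ``payload_length`` bits from a watermarked signal.

    Uses only the watermarked signal and the shared config (band, delta,
    mapping, repetition, key); the original signal is never consulted.
    """
    if cfg.delta is None:
        raise DomainError("cfg.delta is unset; extraction needs the embed-time step")
    n = len(watermarked)
    cap = effective_capacity(cfg, n)
    if payload_length > cap:
        raise CapacityError(
            f"payload_length {payload_length} exceeds the effective capacity {cap}"
        )
    image = to_2d(watermarked, cfg.mapping)
    Q = _basis_for(cfg, image.side)
    M = forward_moments_2d(image.matrix, Q, alpha=cfg.alpha_moment).coefficients

    n_coded = payload_length * cfg.fec_repetition
    hosts = _host_order(cfg, image.side, n_coded)
    rows = np.array([h[0] for h in hosts])
    cols = np.array([h[1] for h in hosts])
    coded = _qim_detect(M[rows, cols], cfg.delta)
    return WatermarkPayload(fec_decode(coded, cfg.fec_repetition))
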
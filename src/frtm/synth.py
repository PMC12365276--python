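"""Seeded synthetic ECG and EEG generators.

These are the download-free test substrate: they emulate the gross
morphology and spectral texture of ambulatory ECG (quasi-periodic
P-QRS-T complexes, baseline wander, sensor noise) and scalp EEG
(band-limited delta/theta/alpha/beta oscillations over 1/f background)
well enough to exercise reconstruction and watermarking, without claiming
physiological fidelity.

The ECG model sums five Gaussian bumps per beat on the beat-phase axis —
a standard simplified surrogate for the PQRST complex — plus a
low-frequency baseline sine and white noise.  The EEG model sums a few
random-phase sinusoids per frequency band, with amplitude set by the
band's configured power, over 1/f^exponent noise shaped in the frequency
domain.  Both are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .transform import Signal1D

__all__ = ["SynthSpec", "synth_ecg", "synth_eeg", "synthesize"]

#: Per-wave Gaussian bump parameters on the beat-phase axis theta in [0, 1):
#: (center phase, amplitude in R-peak units, width in phase units).
ECG_WAVES = {
    "P": (0.18, 0.12, 0.030),
    "Q": (0.27, -0.15, 0.010),
    "R": (0.30, 1.00, 0.012),
    "S": (0.33, -0.20, 0.010),
    "T": (0.55, 0.30, 0.055),
}

#: EEG frequency bands (Hz) and default relative powers; alpha dominates,
#: as in relaxed wakeful recordings.
EEG_BANDS = {
    "delta": ((1.0, 4.0), 1.0),
    "theta": ((4.0, 8.0), 0.5),
    "alpha": ((8.0, 13.0), 2.0),
    "beta": ((13.0, 30.0), 0.3),
}


@dataclass
class SynthSpec:
    """Everything a generator run depends on.

    ECG fields are ignored by :func:`synth_eeg` and vice versa.  Amplitude
    units are arbitrary (R peak = 1 for ECG); ``noise_sd`` is the standard
    deviation of the additive white noise in those units.
    """

    kind: str = "ecg"
    n_samples: int = 1024
    sample_rate_hz: float = 360.0
    seed: int = 0
    noise_sd: float = 0.01
    # ECG
    heart_rate_bpm: float = 60.0
    wave_params: dict = field(default_factory=lambda: dict(ECG_WAVES))
    baseline_amplitude: float = 0.05
    baseline_freq_hz: float = 0.3
    # EEG
    band_powers: dict = field(default_factory=lambda: {k: v[1] for k, v in EEG_BANDS.items()})
    one_over_f_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("ecg", "eeg"):
            raise DomainError(f"kind must be 'ecg' or 'eeg', got {self.kind!r}")
        if self.n_samples < 2:
            raise DomainError(f"n_samples must be >= 2, got {self.n_samples}")
        if not self.sample_rate_hz > 0:
            raise DomainError("sample_rate_hz must be positive")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")


def synth_ecg(spec: SynthSpec) -> Signal1D:
    """Quasi-periodic PQRST train with baseline wander and white noise."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_samples) / spec.sample_rate_hz
    beat_period = 60.0 / spec.heart_rate_bpm
    # small seeded beat-to-beat period jitter (2%) makes the train quasi-periodic
    n_beats = int(np.ceil(t[-1] / beat_period)) + 2
    jitter = rng.normal(1.0, 0.02, size=n_beats)
    periods = beat_period * jitter
    onsets = np.concatenate([[0.0], np.cumsum(periods)])

    s = np.zeros_like(t)
    for k in range(n_beats):
        phase = (t - onsets[k]) / periods[k]
        in_beat = (phase > -0.5) & (phase < 1.5)
        for center, amp, width in spec.wave_params.values():
            s[in_beat] += amp * np.exp(-0.5 * ((phase[in_beat] - center) / width) ** 2)
    s += spec.baseline_amplitude * np.sin(2 * np.pi * spec.baseline_freq_hz * t)
    if spec.noise_sd > 0:
        s += rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
    return Signal1D(s, sample_rate_hz=spec.sample_rate_hz, label=f"synth-ecg-{spec.seed}")


def synth_eeg(spec: SynthSpec) -> Signal1D:
    """Band-limited oscillations over 1/f background noise."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_samples) / spec.sample_rate_hz
    s = np.zeros_like(t)
    for name, ((f_lo, f_hi), _default) in EEG_BANDS.items():
        power = float(spec.band_powers.get(name, 0.0))
        if power <= 0:
            continue
        n_tones = 5
        freqs = rng.uniform(f_lo, f_hi, size=n_tones)
        phases = rng.uniform(0, 2 * np.pi, size=n_tones)
        amp = np.sqrt(power / n_tones)
        for f, ph in zip(freqs, phases):
            s += amp * np.sin(2 * np.pi * f * t + ph)
    if spec.noise_sd > 0:
        # 1/f^beta noise: shape white Gaussian spectrum, scale to noise_sd
        white = rng.normal(0.0, 1.0, size=spec.n_samples)
        spectrum = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(spec.n_samples, d=1.0 / spec.sample_rate_hz)
        shaping = np.ones_like(freqs)
        shaping[1:] = freqs[1:] ** (-spec.one_over_f_exponent / 2.0)
        shaping[0] = 0.0
        pink = np.fft.irfft(spectrum * shaping, n=spec.n_samples)
        sd = pink.std()
        if sd > 0:
            s += spec.noise_sd * pink / sd
    return Signal1D(s, sample_rate_hz=spec.sample_rate_hz, label=f"synth-eeg-{spec.seed}")


def synthesize(spec: SynthSpec) -> Signal1D:
    """Dispatch on ``spec.kind``."""
    return synth_ecg(spec) if spec.kind == "ecg" else synth_eeg(spec)
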
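"""Plain-text signal I/O plus optional WFDB / EDF readers.

CSV is the canonical interchange format: one real value per line, written
with 17 significant digits so a write/read cycle is lossless.  The WFDB
and EDF readers cover the ambulatory-ECG and scalp-EEG recordings this
package is aimed at; they are optional features (install extras
``frtm[physio]``) and never touch the network — files must already be
present locally.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import DomainError, FormatError
from .transform import Signal1D

__all__ = ["read_csv", "write_csv", "read_wfdb", "read_edf"]


def read_csv(path) -> Signal1D:
    """Read a single-column CSV of real values into a signal."""
    path = Path(path)
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: not a real number: {text!r}"
                ) from None
    if not values:
        raise FormatError(f"{path}: no samples found")
    return Signal1D(np.array(values), label=path.stem)


def write_csv(path, signal: Signal1D) -> None:
    """Write one sample per line at 17 significant digits (lossless)."""
    path = Path(path)
    with open(path, "w") as fh:
        for v in signal.samples:
            fh.write(f"{v:.17g}\n")


def _window(samples: np.ndarray, start: int, length: int | None) -> np.ndarray:
    if start < 0 or start >= samples.size:
        raise DomainError(f"window start {start} outside record of {samples.size} samples")
    if length is None:
        return samples[start:]
    if length < 2 or start + length > samples.size:
        raise DomainError(
            f"window [{start}, {start + length}) outside record of {samples.size} samples"
        )
    return samples[start: start + length]


def read_wfdb(record_path, channel: int = 0, start: int = 0,
              length: int | None = None) -> Signal1D:
    """Read one channel of a local WFDB record (e.g. an MIT-BIH excerpt).

    Requires the optional ``wfdb`` package (extras ``frtm[physio]``).
    ``start``/``length`` select a window so desk-scale transform orders
    apply to long ambulatory records.
    """
    record_path = Path(record_path)
    if not record_path.with_suffix(".hea").exists() and not record_path.exists():
        raise FileNotFoundError(f"no WFDB record at {record_path}")
    try:
        import wfdb
    except ImportError as err:
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package; "
            "install with: pip install frtm[physio]"
        ) from err
    record = wfdb.rdrecord(str(record_path))
    if not 0 <= channel < record.n_sig:
        raise DomainError(f"channel {channel} out of range (record has {record.n_sig})")
    samples = np.asarray(record.p_signal[:, channel], dtype=float)
    return Signal1D(_window(samples, start, length), sample_rate_hz=float(record.fs),
                    label=f"{record_path.stem}:ch{channel}")


def read_edf(path, channel: int = 0, start: int = 0,
             length: int | None = None) -> Signal1D:
    """Read one channel of a local EDF recording (e.g. a scalp-EEG file).

    Requires ``mne`` (extras ``frtm[physio]``); the sampling rate is taken
    from the file header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no EDF file at {path}")
    try:
        import mne
    except ImportError as err:
        raise ImportError(
            "reading EDF files requires the optional 'mne' package; "
            "install with: pip install frtm[physio]"
        ) from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()
    if not 0 <= channel < data.shape[0]:
        raise DomainError(f"channel {channel} out of range (file has {data.shape[0]})")
    samples = np.asarray(data[channel], dtype=float)
    return Signal1D(_window(samples, start, length),
                    sample_rate_hz=float(raw.info["sfreq"]),
                    label=f"{path.stem}:ch{channel}")
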
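import numpy as np
import pytest

from frtm import BasisConfig, SynthSpec, orthonormal_basis, synth_ecg


@pytest.fixture(scope="session")
def q512():
    """Full-order orthonormal analysis basis for N=512, alpha=1 (shared)."""
    return orthonormal_basis(BasisConfig.full_order(1.0, 512))


@pytest.fixture(scope="session")
def ecg512():
    return synth_ecg(SynthSpec(kind="ecg", n_samples=512, seed=7))


def write_minimal_edf(path, channels, fs):
    """Write a synthetic single-record EDF file (test fixture, generated
    programmatically; physical range +-1000 uV mapped onto 16-bit ints)."""
    nsig = len(channels)
    nsamp = len(channels[0])

    def pad(s, n):
        return str(s).ljust(n)[:n].encode("ascii")

    def fields(vals, w):
        return b"".join(pad(v, w) for v in vals)

    hdr = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("X X X", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(256 * (nsig + 1), 8), pad("", 44), pad("1", 8),
        pad(nsamp / fs, 8), pad(nsig, 4),
        fields([f"ch{i}" for i in range(nsig)], 16),
        fields([""] * nsig, 80), fields(["uV"] * nsig, 8),
        fields([-1000] * nsig, 8), fields([1000] * nsig, 8),
        fields([-32768] * nsig, 8), fields([32767] * nsig, 8),
        fields([""] * nsig, 80), fields([nsamp] * nsig, 8),
        fields([""] * nsig, 32),
    ])
    with open(path, "wb") as fh:
        fh.write(hdr)
        for ch in channels:
            dig = np.clip(np.round((np.asarray(ch) + 1000) / 2000 * 65535 - 32768),
                          -32768, 32767).astype("<i2")
            fh.write(dig.tobytes())
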
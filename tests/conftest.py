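"""Shared fixtures: small synthetic recordings and a minimal EDF writer.

All fixtures are generated programmatically; nothing is read from disk
except files the tests themselves write.
"""

from __future__ import annotations

import struct

import numpy as np
import pytest

from interbrain.signal_model import DyadEpochs, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_recording(rng):
    """2 channels x 8 trials x 200 samples at 100 Hz, onset at sample 50."""
    data = rng.standard_normal((2, 8, 200))
    return Recording("p1", ["C3", "C4"], data, srate=100.0, t0_index=50)


@pytest.fixture
def small_dyad(rng):
    data_a = rng.standard_normal((1, 10, 300))
    data_b = rng.standard_normal((1, 10, 300))
    return DyadEpochs(
        a=Recording("a", ["Cz"], data_a, 100.0, 100),
        b=Recording("b", ["Cz"], data_b, 100.0, 100),
    )


def write_edf(path, data, srate, labels=None):
    """Write a minimal continuous EDF file (synthetic fixture writer).

    ``data`` is (n_channels, n_samples) in microvolts; ``srate`` must divide
    into 1-second records.  Physical range +-1000 uV over the full 16-bit
    digital range, so the quantisation step is ~0.03 uV.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    spr = int(round(srate))  # samples per 1 s record
    if n_samp % spr:
        raise ValueError("data length must be a whole number of 1 s records")
    n_rec = n_samp // spr
    labels = labels or [f"EEG {i}" for i in range(n_ch)]
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767

    def pad(value, width):
        s = str(value)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X", 80), pad("X", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(256 * (n_ch + 1), 8), pad("", 44),
        pad(n_rec, 8), pad("1", 8), pad(n_ch, 4),
    ])
    fields = [
        [pad(lb, 16) for lb in labels],
        [pad("", 80)] * n_ch,
        [pad("uV", 8)] * n_ch,
        [pad(phys_min, 8)] * n_ch,
        [pad(phys_max, 8)] * n_ch,
        [pad(dig_min, 8)] * n_ch,
        [pad(dig_max, 8)] * n_ch,
        [pad("", 80)] * n_ch,
        [pad(spr, 8)] * n_ch,
        [pad("", 32)] * n_ch,
    ]
    header += b"".join(b"".join(f) for f in fields)

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data - phys_min) * scale + dig_min), dig_min, dig_max
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for ch in range(n_ch):
                fh.write(struct.pack(f"<{spr}h", *digital[ch, r * spr : (r + 1) * spr]))
    return path
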
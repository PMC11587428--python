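"""Shared fixtures: tiny EEG signals and a minimal EDF writer.

All fixture data is generated at test time; the EDF writer emits just
enough of the 16-bit EDF standard to exercise the reader on a synthetic
polysomnography-like file.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest


def write_minimal_edf(path, channels, data, sampling_rate):
    """Write a minimal valid EDF file (synthetic fixture).

    ``data`` is (n_channels, n_samples) in arbitrary physical units;
    one data record per second.
    """
    data = np.asarray(data, dtype=float)
    ns = len(channels)
    fs = int(sampling_rate)
    n_records = data.shape[1] // fs
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767

    def pad(s, n):
        return s[:n].ljust(n).encode("ascii")

    hdr = b"".join([
        pad("0", 8),
        pad("synthetic patient", 80),
        pad("synthetic recording", 80),
        pad("01.01.20", 8),
        pad("00.00.00", 8),
        pad(str(256 * (1 + ns)), 8),
        pad("", 44),
        pad(str(n_records), 8),
        pad("1", 8),
        pad(str(ns), 4),
    ])
    hdr += b"".join(pad(ch, 16) for ch in channels)
    hdr += b"".join(pad("", 80) for _ in channels)
    hdr += b"".join(pad("uV", 8) for _ in channels)
    hdr += b"".join(pad(str(phys_min), 8) for _ in channels)
    hdr += b"".join(pad(str(phys_max), 8) for _ in channels)
    hdr += b"".join(pad(str(dig_min), 8) for _ in channels)
    hdr += b"".join(pad(str(dig_max), 8) for _ in channels)
    hdr += b"".join(pad("", 80) for _ in channels)
    hdr += b"".join(pad(str(fs), 8) for _ in channels)
    hdr += b"".join(pad("", 32) for _ in channels)

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    dig = np.clip((data - phys_min) * scale + dig_min,
                  dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_records):
            for c in range(ns):
                fh.write(dig[c, r * fs:(r + 1) * fs].tobytes())
    return path


@pytest.fixture
def edf_file(tmp_path):
    """4-channel synthetic EDF at 250 Hz, 10 s, with PSG-style labels."""
    fs = 250
    t = np.arange(fs * 10) / fs
    labels = ["EEG O1-M2", "EEG O2-M1", "EEG C3-M2", "EEG C4-M1"]
    data = np.stack([
        50 * np.sin(2 * np.pi * 10 * t),
        40 * np.sin(2 * np.pi * 6 * t),
        30 * np.sin(2 * np.pi * 12 * t),
        20 * np.sin(2 * np.pi * 3 * t),
    ])
    return write_minimal_edf(tmp_path / "psg.edf", labels, data, fs)


@pytest.fixture
def sinusoid_record():
    import oscipat as op

    fs, dur, f = 250.0, 30.0, 10.0
    t = np.arange(int(fs * dur)) / fs
    return op.SignalRecord("O1", fs, np.sin(2 * np.pi * f * t))


@pytest.fixture(autouse=True)
def _quiet_grid_warning():
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="grid scale spacing", category=UserWarning
        )
        yield
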
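"""Shared fixtures: small trials, reference signals, and an EDF writer.

The EDF writer emits a minimal but standard-conforming file so the reader
can be exercised without shipping binary fixtures; everything is generated
at test time.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from eegdenoise.types import TEN_TWENTY_19, Trial


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_trial(rng) -> Trial:
    """4 channels x 40 samples of band-limited noise, fs 200."""
    data = rng.normal(0, 10, size=(4, 40))
    return Trial(data, fs=200.0, channel_labels=("Fp1", "Fp2", "Cz", "O1"))


@pytest.fixture
def clean_trial() -> Trial:
    from eegdenoise.synth import generate_clean_trial

    return generate_clean_trial(seed=7)


def write_minimal_edf(path: Path, data: np.ndarray, fs: float,
                      labels: list[str]) -> None:
    """Write one-record EDF with physical range chosen to cover the data."""
    n_ch, n_samp = data.shape
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)

    def pad(s: str, n: int) -> bytes:
        return s.encode("ascii")[:n].ljust(n)

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 * (n_ch + 1)), 8), pad("", 44), pad("1", 8),
        pad(str(n_samp / fs), 8), pad(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(pad(lab, 16) for lab in labels),
        b"".join(pad("AgAgCl electrode", 80) for _ in labels),
        b"".join(pad("uV", 8) for _ in labels),
        b"".join(pad(str(phys_min), 8) for _ in labels),
        b"".join(pad(str(phys_max), 8) for _ in labels),
        b"".join(pad(str(dig_min), 8) for _ in labels),
        b"".join(pad(str(dig_max), 8) for _ in labels),
        b"".join(pad("", 80) for _ in labels),
        b"".join(pad(str(n_samp), 8) for _ in labels),
        b"".join(pad("", 32) for _ in labels),
    ])
    digital = np.clip(np.round(data * scale), dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for ch in range(n_ch):
            fh.write(digital[ch].tobytes())


@pytest.fixture
def edf_file(tmp_path, rng) -> Path:
    path = tmp_path / "rec.edf"
    data = rng.normal(0, 20, size=(19, 200))
    write_minimal_edf(path, data, fs=200.0, labels=list(TEN_TWENTY_19))
    return path
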
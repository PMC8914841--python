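"""Core containers: raw recordings and fixed-length trials.

Amplitudes are in microvolts throughout. The canonical trial geometry is
19 channels x 200 samples at 200 Hz (a one-second motor-imagery epoch on a
10-20 montage), but any C >= 2, T >= 16 is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: 19-channel subset of the international 10-20 system, front to back.
TEN_TWENTY_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Channels nearest the eyes; eye-blink artifacts concentrate here.
FRONTAL_CHANNELS = ("Fp1", "Fp2", "F7", "F8")

#: Central-scalp channels; typically the most stable recording sites.
CENTRAL_CHANNELS = ("C3", "Cz", "C4")


def _validate_matrix(data: np.ndarray, labels: Sequence[str], fs: float) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError(f"expected a channels x samples matrix, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError("signal contains non-finite values")
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    if len(labels) != data.shape[0]:
        raise ValueError(
            f"{len(labels)} channel labels for {data.shape[0]} channel rows"
        )
    return data


@dataclass
class RawRecording:
    """A continuous multichannel recording, optionally with trial markers.

    Parameters
    ----------
    data
        channels x samples matrix (microvolts).
    fs
        Sampling rate in Hz.
    channel_labels
        Ordered channel names (10-20 montage for the canonical setup).
    trial_markers
        Optional sample indices where trials start.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    trial_markers: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.data = _validate_matrix(self.data, self.channel_labels, self.fs)
        if self.trial_markers is not None:
            self.trial_markers = tuple(int(m) for m in self.trial_markers)
            for m in self.trial_markers:
                if not 0 <= m < self.data.shape[1]:
                    raise IndexError(f"trial marker {m} outside recording of "
                                     f"{self.data.shape[1]} samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "RawRecording":
        return replace(self, data=data)


@dataclass
class Trial:
    """One fixed-length channels x samples EEG segment (microvolts)."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = field(default=TEN_TWENTY_19)

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.data = _validate_matrix(self.data, self.channel_labels, self.fs)
        c, t = self.data.shape
        if c < 2:
            raise ValueError(f"a trial needs at least 2 channels, got {c}")
        if t < 16:
            raise ValueError(f"a trial needs at least 16 samples, got {t}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "Trial":
        return replace(self, data=data)

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None

    def copy(self) -> "Trial":
        return replace(self, data=self.data.copy())
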
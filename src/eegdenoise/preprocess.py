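"""Standard EEG conditioning ahead of normalization and denoising.

The chain is: band-pass 1-40 Hz (kills 50/60 Hz line noise and slow drift),
common-average re-reference, per-trial baseline removal, and segmentation
into fixed-length trials.
"""

from __future__ import annotations

from scipy import signal

import numpy as np

from .types import RawRecording, Trial


def bandpass_filter(rec: RawRecording, low: float = 1.0, high: float = 40.0) -> RawRecording:
    """Zero-phase 4th-order Butterworth band-pass, applied per channel.

    Forward-backward filtering (``filtfilt`` with even-reflection padding)
    doubles the effective order and cancels phase distortion, so transient
    morphology is preserved.
    """
    nyq = rec.fs / 2.0
    if not 0.0 < low < high < nyq:
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(4, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1, padtype="even")
    return rec.with_data(out)


def rereference(rec: RawRecording) -> RawRecording:
    """Common-average re-reference: subtract the across-channel mean at each sample."""
    if rec.n_channels < 2:
        raise ValueError("common-average reference needs at least 2 channels")
    return rec.with_data(rec.data - rec.data.mean(axis=0, keepdims=True))


def remove_baseline(trial: Trial) -> Trial:
    """Remove each channel's temporal mean over the trial window."""
    return trial.with_data(trial.data - trial.data.mean(axis=1, keepdims=True))


def segment_trials(rec: RawRecording, length: int = 200) -> list[Trial]:
    """Cut a recording into fixed-length trials.

    Trials start at ``rec.trial_markers`` when present; otherwise the
    recording is tiled non-overlappingly from sample 0. Markers with fewer
    than ``length`` samples remaining raise; trailing remainders of a tiling
    are dropped.
    """
    if length < 1:
        raise ValueError("trial length must be positive")
    n = rec.n_samples
    if rec.trial_markers is not None:
        starts = list(rec.trial_markers)
        for s in starts:
            if s + length > n:
                raise IndexError(
                    f"marker {s} leaves {n - s} samples, fewer than trial length {length}"
                )
    else:
        starts = list(range(0, n - length + 1, length))
        if not starts:
            raise IndexError(f"recording of {n} samples shorter than trial length {length}")
    return [
        Trial(rec.data[:, s:s + length].copy(), rec.fs, rec.channel_labels)
        for s in starts
    ]


def preprocess_recording(rec: RawRecording, low: float = 1.0, high: float = 40.0,
                         trial_length: int = 200) -> list[Trial]:
    """Full conditioning chain: band-pass, re-reference, segment, de-baseline."""
    rec = rereference(bandpass_filter(rec, low, high))
    return [remove_baseline(t) for t in segment_trials(rec, trial_length)]
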
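"""SETET normalization: entropy- and energy-thresholded max-abs scaling.

Plain max-abs normalization of an EEG trial is hostage to its largest
artifact: one 300 uV blink shrinks every other channel into a sliver of the
[-1, 1] range. SETET instead flags (channel, segment) blocks that look like
artifacts -- channel SampEn below a threshold ``k`` AND segment mean |x|
energy above a threshold ``e`` -- and computes the normalization coefficient
``m`` as the max |x| over the *unflagged* blocks only. The trial is then
scaled as S = X / m, and X is recovered exactly as S * m.

Flagged samples are excluded from the m computation but never clipped or
altered; their normalized values may exceed 1 in magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sample_entropy import SampEnParams, channel_entropies
from .types import Trial


@dataclass(frozen=True)
class EntropyThresholdInputs:
    """Mean SampEn of reference trials: all channels, frontal group, central group.

    ``delta`` quantifies "not much difference" between the three means.
    """

    SE_a: float
    SE_f: float
    SE_c: float
    delta: float = 0.1

    def __post_init__(self) -> None:
        for name in ("SE_a", "SE_f", "SE_c"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class SetetConfig:
    """Thresholds of the SETET screen.

    k
        SampEn threshold: channels below it are artifact candidates. 0.3
        separates normal EEG (roughly 0.3-1.5 on one-second trials) from
        blink-dominated channels (below 0.2-0.3).
    e
        Mean-L1-energy threshold in uV: normal trials sit around 20-30,
        artifact segments exceed 50.
    n_segments
        Segments per channel; 10 gives 20-sample blocks at T=200, matching
        the short-transient scale of blinks.
    """

    k: float = 0.3
    e: float = 50.0
    n_segments: int = 10

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.e <= 0:
            raise ValueError("e must be positive")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")


@dataclass
class SegmentFlagMask:
    """Per-(channel, segment) abnormality flags plus the statistics behind them."""

    flags: np.ndarray            # bool, channels x n_segments
    entropies: np.ndarray        # per-channel SampEn
    energies: np.ndarray         # channels x n_segments mean |x|
    n_segments: int

    def __post_init__(self) -> None:
        if self.flags.shape != self.energies.shape:
            raise ValueError("flags and energies shapes differ")
        if self.flags.shape[1] != self.n_segments:
            raise ValueError("mask width differs from n_segments")


@dataclass
class NormalizationResult:
    """Normalized trial S = X / m with everything needed to invert exactly."""

    S: Trial
    m: float
    mask: SegmentFlagMask
    config: SetetConfig

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("normalization coefficient must be positive")


def select_entropy_threshold(inputs: EntropyThresholdInputs) -> float:
    """Pick the SampEn threshold k from reference-group mean entropies.

    When SE_a, SE_f, SE_c agree to within delta, the frontal mean SE_f is the
    threshold; otherwise the midpoint of SE_a and SE_c, which lies between
    them.
    """
    vals = (inputs.SE_a, inputs.SE_f, inputs.SE_c)
    if max(vals) - min(vals) <= inputs.delta:
        return inputs.SE_f
    return (inputs.SE_a + inputs.SE_c) / 2.0


def segment_slices(n_samples: int, n_segments: int) -> list[slice]:
    """Contiguous near-equal blocks; the last block absorbs any remainder."""
    if n_segments > n_samples:
        raise ValueError(f"n_segments={n_segments} exceeds signal length {n_samples}")
    width = n_samples // n_segments
    slices = [slice(j * width, (j + 1) * width) for j in range(n_segments)]
    slices[-1] = slice((n_segments - 1) * width, n_samples)
    return slices


def segment_mean_energy(x: np.ndarray, n_segments: int) -> np.ndarray:
    """Mean L1 energy (mean |x|) of each contiguous segment."""
    x = np.asarray(x, dtype=float).ravel()
    return np.array([np.mean(np.abs(x[s])) for s in segment_slices(x.size, n_segments)])


def flag_segments(trial: Trial, config: SetetConfig = SetetConfig(),
                  params: SampEnParams = SampEnParams()) -> SegmentFlagMask:
    """Two-stage screen: low channel entropy, then high segment energy.

    A (channel, segment) is flagged iff the channel's SampEn is below k AND
    that segment's mean |x| exceeds e. The energy gate "filters back" normal
    segments of a low-entropy channel, so an over-large k is forgiving.
    """
    ent = channel_entropies(trial, params)
    energies = np.stack([segment_mean_energy(ch, config.n_segments) for ch in trial.data])
    low_entropy = ent < config.k
    flags = low_entropy[:, None] & (energies > config.e)
    return SegmentFlagMask(flags=flags, entropies=ent, energies=energies,
                           n_segments=config.n_segments)


def compute_normalization_coefficient(trial: Trial, mask: SegmentFlagMask) -> float:
    """Max |x| over unflagged samples; falls back to the global max (or 1) if none."""
    keep = np.ones_like(trial.data, dtype=bool)
    slices = segment_slices(trial.n_samples, mask.n_segments)
    for c in range(trial.n_channels):
        for j, s in enumerate(slices):
            if mask.flags[c, j]:
                keep[c, s] = False
    if keep.any():
        m = float(np.max(np.abs(trial.data[keep])))
    else:
        m = float(np.max(np.abs(trial.data)))
    if m == 0.0:
        return 1.0  # all-zero trial: identity scaling keeps division safe
    return m


def normalize(trial: Trial, m: float, mask: SegmentFlagMask | None = None,
              config: SetetConfig = SetetConfig()) -> NormalizationResult:
    """S = X / m. The coefficient and mask are retained for exact inversion."""
    if m <= 0:
        raise ValueError(f"normalization coefficient must be positive, got {m}")
    if mask is None:
        mask = SegmentFlagMask(
            flags=np.zeros((trial.n_channels, config.n_segments), dtype=bool),
            entropies=np.full(trial.n_channels, np.nan),
            energies=np.zeros((trial.n_channels, config.n_segments)),
            n_segments=config.n_segments,
        )
    return NormalizationResult(S=trial.with_data(trial.data / m), m=m,
                               mask=mask, config=config)


def setet_normalize(trial: Trial, config: SetetConfig = SetetConfig(),
                    params: SampEnParams = SampEnParams()) -> NormalizationResult:
    """Full SETET pass: flag, compute m from normal blocks, scale."""
    mask = flag_segments(trial, config, params)
    m = compute_normalization_coefficient(trial, mask)
    return normalize(trial, m, mask, config)


def denormalize(result: NormalizationResult) -> Trial:
    """Exact inverse of :func:`normalize`: X = S * m."""
    return result.S.with_data(result.S.data * result.m)
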
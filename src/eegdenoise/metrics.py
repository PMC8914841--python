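"""Denoising fidelity statistics: mean correlation, RMSE, band power.

Mean correlation averages the per-channel Pearson correlation between
original and denoised signals over channels, then over trials. RMSE takes,
per trial, the square root of the channel-averaged summed squared residual
(the inner time sum is not normalized), then averages the roots over trials.
The band-power report compares mean power spectral density in named
frequency bands over channel groups, the frequency-domain check that
artifact energy went down while physiological bands survived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .types import Trial

#: Default bands (Hz): blink/eye-movement range, motor-imagery range, EMG range.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "low_1_4": (1.0, 4.0),
    "mid_5_25": (5.0, 25.0),
    "high_gt_30": (30.0, np.inf),
}


def _stack(x: Sequence[Trial] | np.ndarray) -> np.ndarray:
    if isinstance(x, np.ndarray):
        arr = x if x.ndim == 3 else x[None]
    else:
        arr = np.stack([t.data for t in x])
    return np.asarray(arr, dtype=float)


def _aligned(x, xp) -> tuple[np.ndarray, np.ndarray]:
    a, b = _stack(x), _stack(xp)
    if a.shape != b.shape:
        raise ValueError(f"misaligned trial collections: {a.shape} vs {b.shape}")
    if a.shape[0] == 0:
        raise ValueError("empty trial collection")
    return a, b


def channel_correlations(x, xp) -> np.ndarray:
    """Pearson correlation per (trial, channel); 0 where either side is constant."""
    a, b = _aligned(x, xp)
    ac = a - a.mean(axis=2, keepdims=True)
    bc = b - b.mean(axis=2, keepdims=True)
    num = (ac * bc).sum(axis=2)
    den = np.sqrt((ac ** 2).sum(axis=2) * (bc ** 2).sum(axis=2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return r


def mean_correlation(x, xp) -> float:
    """Per-channel Pearson correlation averaged over channels then trials."""
    return float(channel_correlations(x, xp).mean())


def rmse(x, xp) -> float:
    """Mean over trials of sqrt(sum_c ||X_kc - X'_kc||^2 / N), N = channel count."""
    a, b = _aligned(x, xp)
    n = a.shape[1]
    per_trial = np.sqrt(((a - b) ** 2).sum(axis=(1, 2)) / n)
    return float(per_trial.mean())


@dataclass
class BandPowerReport:
    """Mean PSD power per (band, channel group) for two trial collections."""

    bands: dict[str, tuple[float, float]]
    groups: dict[str, tuple[int, ...]]
    power_original: dict[str, dict[str, float]]   # group -> band -> power
    power_denoised: dict[str, dict[str, float]]
    ratio: dict[str, dict[str, float]] = field(init=False)

    def __post_init__(self) -> None:
        self.ratio = {
            g: {
                b: (self.power_denoised[g][b] / self.power_original[g][b]
                    if self.power_original[g][b] > 0 else np.nan)
                for b in self.bands
            }
            for g in self.groups
        }


def band_power(trials, fs: float, band: tuple[float, float],
               channel_idx: Sequence[int]) -> float:
    """Mean Hann-windowed periodogram power in ``band`` over selected channels."""
    arr = _stack(trials)[:, list(channel_idx), :]
    freqs, psd = signal.periodogram(arr, fs=fs, window="hann", axis=-1)
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        raise ValueError(f"band {band} Hz contains no frequency bins at fs={fs}")
    return float(psd[..., sel].sum(axis=-1).mean())


def band_power_report(
    x: Sequence[Trial],
    xp: Sequence[Trial],
    fs: float | None = None,
    bands: Mapping[str, tuple[float, float]] | None = None,
    channel_groups: Mapping[str, Sequence[str]] | None = None,
) -> BandPowerReport:
    """Compare band powers of original vs denoised trials per channel group."""
    xs, xps = list(x), list(xp)
    if len(xs) != len(xps) or not xs:
        raise ValueError("need equally many (>=1) original and denoised trials")
    fs = fs if fs is not None else xs[0].fs
    bands = dict(bands) if bands is not None else dict(DEFAULT_BANDS)
    nyq = fs / 2
    for name, (lo, hi) in bands.items():
        if lo >= nyq:
            raise ValueError(f"band {name} starts at {lo} Hz, beyond Nyquist {nyq} Hz")
        bands[name] = (lo, min(hi, nyq))
    if channel_groups is None:
        channel_groups = {"all": list(xs[0].channel_labels)}
    groups: dict[str, tuple[int, ...]] = {}
    for gname, labels in channel_groups.items():
        if not labels:
            raise ValueError(f"channel group {gname!r} is empty")
        groups[gname] = tuple(xs[0].channel_index(c) for c in labels)
    orig = {g: {b: band_power(xs, fs, bands[b], idx) for b in bands}
            for g, idx in groups.items()}
    deno = {g: {b: band_power(xps, fs, bands[b], idx) for b in bands}
            for g, idx in groups.items()}
    return BandPowerReport(bands=bands, groups=groups,
                           power_original=orig, power_denoised=deno)


@dataclass
class EvaluationReport:
    """Summary statistics of one denoising run."""

    correlations: np.ndarray        # trials x channels
    mean_correlation: float
    rmse: float
    band_report: BandPowerReport | None = None


def evaluate(x: Sequence[Trial], xp: Sequence[Trial],
             with_bands: bool = True,
             channel_groups: Mapping[str, Sequence[str]] | None = None) -> EvaluationReport:
    corr = channel_correlations(x, xp)
    rep = band_power_report(x, xp, channel_groups=channel_groups) if with_bands else None
    return EvaluationReport(
        correlations=corr,
        mean_correlation=float(corr.mean()),
        rmse=rmse(x, xp),
        band_report=rep,
    )
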
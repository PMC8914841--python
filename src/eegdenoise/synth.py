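"""Paired clean/noisy synthetic motor-imagery EEG.

Clean trials are sums of randomized-phase band-limited oscillations (delta,
theta, alpha, beta) plus 1/f pink noise, spatially smoothed across
neighboring electrodes, and rescaled so each trial's mean L1 energy lies in
the normal 20-30 uV range with per-channel sample entropy in the normal
(0.3, 1.5] regime. On top of these, four artifact families can be injected
additively: slow frontal eye-blink transients (1-4 Hz, hundreds of uV),
high-frequency EMG bursts (> 30 Hz), 50 Hz power-line sinusoids, and
periodic heartbeat spikes. The noisy minus the clean trial is exactly the
injected waveform, which makes the pairs usable as supervised denoising
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal as sps

from .types import TEN_TWENTY_19, Trial

#: Band edges (Hz) and relative amplitude weights of the clean-signal mixture.
_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
}

#: Per-channel gain of a blink transient: strongest at the eyes, decaying
#: toward posterior sites.
_BLINK_GAINS: dict[str, float] = {
    "Fp1": 1.0, "Fp2": 1.0, "F7": 0.55, "F8": 0.55,
    "F3": 0.25, "Fz": 0.2, "F4": 0.25,
}


@dataclass(frozen=True)
class CleanEEGConfig:
    """Geometry and spectral mixture of simulated clean trials.

    ``band_weights`` are relative amplitudes of the rhythmic components;
    ``pink_weight`` scales the broadband 1/f floor that keeps the signal
    irregular enough to stay in the normal sample-entropy range.
    ``l1_range`` is the interval the per-trial mean L1 energy (mean |x|,
    uV) is drawn from.
    """

    n_channels: int = 19
    n_samples: int = 200
    fs: float = 200.0
    band_weights: Mapping[str, float] = field(
        default_factory=lambda: {"delta": 0.4, "theta": 0.5, "alpha": 1.0, "beta": 0.6})
    pink_weight: float = 1.0
    spatial_rho: float = 0.35
    l1_range: tuple[float, float] = (22.0, 28.0)
    channel_labels: tuple[str, ...] = TEN_TWENTY_19

    def __post_init__(self) -> None:
        if self.n_channels != len(self.channel_labels):
            # front-to-back subset of the 10-20 montage keeps frontal sites
            # available for blink injection on reduced geometries
            labels = (TEN_TWENTY_19[:self.n_channels]
                      if self.n_channels <= len(TEN_TWENTY_19)
                      else tuple(f"ch{i}" for i in range(self.n_channels)))
            object.__setattr__(self, "channel_labels", labels)
        lo, hi = self.l1_range
        if not 0 < lo <= hi:
            raise ValueError("l1_range must be positive and ordered")


@dataclass(frozen=True)
class ArtifactSpec:
    """One artifact to inject: kind, placement, scale, timing, frequency.

    Fields left ``None`` are filled with kind-appropriate defaults (and
    seed-derived timing) by the injectors.
    """

    kind: str
    channels: tuple[str, ...] | None = None
    amplitude: float = 0.0
    onset: int | None = None
    duration: int | None = None
    freq: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("blink", "emg", "line", "heartbeat", "none"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-variance randomized-phase noise confined to a frequency band."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    spec = np.zeros(freqs.size, dtype=complex)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    spec[sel] = rng.normal(size=sel.sum()) + 1j * rng.normal(size=sel.sum())
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float] = (1.0, 45.0)) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping with seeded phases."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    spec = np.zeros(freqs.size, dtype=complex)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    amp = 1.0 / np.sqrt(freqs[sel])
    spec[sel] = amp * (rng.normal(size=sel.sum()) + 1j * rng.normal(size=sel.sum()))
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_clean_trial(config: CleanEEGConfig = CleanEEGConfig(),
                         seed: int = 0) -> Trial:
    """One clean trial; identical seeds give identical trials."""
    rng = np.random.default_rng(seed)
    c, n, fs = config.n_channels, config.n_samples, config.fs
    data = np.zeros((c, n))
    for ch in range(c):
        x = np.zeros(n)
        for name, w in config.band_weights.items():
            x += w * _band_noise(rng, n, fs, _BANDS[name])
        x += config.pink_weight * _pink_noise(rng, n, fs)
        data[ch] = x
    # spatial smoothing: mix each channel with its montage neighbors
    idx = np.arange(c)
    mix = config.spatial_rho ** np.abs(idx[:, None] - idx[None, :])
    mix /= mix.sum(axis=1, keepdims=True)
    data = mix @ data
    target = rng.uniform(*config.l1_range)
    data *= target / np.mean(np.abs(data))
    return Trial(data, fs, config.channel_labels)


# ---------------------------------------------------------------------------
# Artifact injectors. Each builds the additive waveform, so noisy - clean is
# exactly the artifact, and each is the identity at amplitude 0.


def _resolve_window(trial: Trial, spec: ArtifactSpec, default_dur: int) -> tuple[int, int]:
    dur = spec.duration if spec.duration is not None else min(default_dur, trial.n_samples)
    if spec.onset is not None:
        onset = spec.onset
    else:
        hi = trial.n_samples - dur
        onset = int(np.random.default_rng(spec.seed).integers(0, max(hi, 0) + 1))
    if onset < 0 or dur < 1 or onset + dur > trial.n_samples:
        raise ValueError(
            f"artifact window [{onset}, {onset + dur}) outside trial of "
            f"{trial.n_samples} samples")
    return onset, dur


def blink_waveform(trial: Trial, spec: ArtifactSpec) -> np.ndarray:
    """Smooth low-frequency frontal transient (Hann lobe, ~1-4 Hz content)."""
    channels = spec.channels or tuple(
        c for c in _BLINK_GAINS if c in trial.channel_labels)
    if not channels:
        raise ValueError("no frontal channels available for a blink")
    amp = spec.amplitude
    onset, dur = _resolve_window(trial, spec, default_dur=int(0.6 * trial.fs))
    lobe = np.sin(np.pi * np.arange(dur) / (dur - 1)) ** 2
    wave = np.zeros_like(trial.data)
    for ch in channels:
        i = trial.channel_index(ch)
        wave[i, onset:onset + dur] = amp * _BLINK_GAINS.get(ch, 0.4) * lobe
    return wave


def inject_blink(trial: Trial, spec: ArtifactSpec | None = None) -> Trial:
    spec = spec or ArtifactSpec(kind="blink", amplitude=600.0)
    return trial.with_data(trial.data + blink_waveform(trial, spec))


def emg_waveform(trial: Trial, spec: ArtifactSpec) -> np.ndarray:
    """Band-limited (> 30 Hz) noise burst with a tapered envelope."""
    channels = spec.channels or tuple(
        c for c in ("T3", "T4", "F7", "F8") if c in trial.channel_labels) \
        or trial.channel_labels[:2]
    onset, dur = _resolve_window(trial, spec, default_dur=int(0.4 * trial.fs))
    cutoff = spec.freq if spec.freq is not None else 30.0
    rng = np.random.default_rng(spec.seed)
    sos = sps.butter(4, cutoff, btype="highpass", fs=trial.fs, output="sos")
    env = sps.windows.tukey(dur, alpha=0.5)
    wave = np.zeros_like(trial.data)
    for ch in channels:
        i = trial.channel_index(ch)
        burst = sps.sosfiltfilt(sos, rng.normal(size=dur))
        sd = burst.std()
        if sd > 0:
            burst *= spec.amplitude / sd
        wave[i, onset:onset + dur] = burst * env
    return wave


def inject_emg(trial: Trial, spec: ArtifactSpec | None = None) -> Trial:
    spec = spec or ArtifactSpec(kind="emg", amplitude=40.0)
    return trial.with_data(trial.data + emg_waveform(trial, spec))


def line_waveform(trial: Trial, spec: ArtifactSpec) -> np.ndarray:
    """Power-line sinusoid (default 50 Hz), common phase across channels."""
    freq = spec.freq if spec.freq is not None else 50.0
    phase = np.random.default_rng(spec.seed).uniform(0, 2 * np.pi)
    t = np.arange(trial.n_samples) / trial.fs
    row = spec.amplitude * np.sin(2 * np.pi * freq * t + phase)
    channels = spec.channels or trial.channel_labels
    wave = np.zeros_like(trial.data)
    for ch in channels:
        wave[trial.channel_index(ch)] = row
    return wave


def inject_line_noise(trial: Trial, spec: ArtifactSpec | None = None) -> Trial:
    spec = spec or ArtifactSpec(kind="line", amplitude=10.0)
    return trial.with_data(trial.data + line_waveform(trial, spec))


def heartbeat_waveform(trial: Trial, spec: ArtifactSpec) -> np.ndarray:
    """Equally spaced spike-like events at a cardiac rate (default 1.2 Hz)."""
    rate = spec.freq if spec.freq is not None else 1.2
    period = trial.fs / rate
    onset = spec.onset if spec.onset is not None else int(
        np.random.default_rng(spec.seed).integers(0, int(period)))
    width = spec.duration if spec.duration is not None else max(int(0.04 * trial.fs), 5)
    template = spec.amplitude * sps.windows.general_gaussian(2 * width + 1, p=1.5,
                                                            sig=width / 2.5)
    channels = spec.channels or tuple(
        c for c in ("T3", "T4") if c in trial.channel_labels) or trial.channel_labels[:1]
    wave = np.zeros_like(trial.data)
    centers = []
    k = 0
    while onset + k * period < trial.n_samples:
        centers.append(int(round(onset + k * period)))
        k += 1
    for ch in channels:
        i = trial.channel_index(ch)
        for c0 in centers:
            lo, hi = max(0, c0 - width), min(trial.n_samples, c0 + width + 1)
            wave[i, lo:hi] += template[lo - (c0 - width):hi - (c0 - width)]
    return wave


def inject_heartbeat(trial: Trial, spec: ArtifactSpec | None = None) -> Trial:
    spec = spec or ArtifactSpec(kind="heartbeat", amplitude=30.0)
    return trial.with_data(trial.data + heartbeat_waveform(trial, spec))


_WAVEFORMS = {
    "blink": blink_waveform,
    "emg": emg_waveform,
    "line": line_waveform,
    "heartbeat": heartbeat_waveform,
}

#: Default amplitude per artifact kind (uV): blinks reach hundreds of uV,
#: EMG bursts tens, line and heartbeat more modest.
DEFAULT_AMPLITUDES = {"blink": 600.0, "emg": 40.0, "line": 10.0, "heartbeat": 30.0}


def inject(trial: Trial, spec: ArtifactSpec) -> Trial:
    """Dispatch on ``spec.kind``; 'none' returns the trial unchanged."""
    if spec.kind == "none":
        return trial.copy()
    return trial.with_data(trial.data + _WAVEFORMS[spec.kind](trial, spec))


@dataclass
class PairedDataset:
    """Aligned clean/noisy trials with the artifact ground truth that links them."""

    clean: list[Trial]
    noisy: list[Trial]
    specs: list[ArtifactSpec]
    seed: int
    config: CleanEEGConfig

    def __post_init__(self) -> None:
        if not len(self.clean) == len(self.noisy) == len(self.specs):
            raise ValueError("clean, noisy and specs must be aligned")

    def __len__(self) -> int:
        return len(self.clean)

    def clean_array(self) -> np.ndarray:
        return np.stack([t.data for t in self.clean])

    def noisy_array(self) -> np.ndarray:
        return np.stack([t.data for t in self.noisy])


def make_paired_dataset(
    n_trials: int,
    artifact_mix: Mapping[str, float],
    config: CleanEEGConfig = CleanEEGConfig(),
    seed: int = 0,
    amplitudes: Mapping[str, float] | None = None,
) -> PairedDataset:
    """Draw artifact kinds per trial from ``artifact_mix`` and build pairs.

    ``artifact_mix`` maps kind (including 'none') to proportion; proportions
    must sum to 1. Everything is reproducible from ``seed``.
    """
    kinds = list(artifact_mix)
    probs = np.array([artifact_mix[k] for k in kinds], dtype=float)
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"artifact mix proportions must be >= 0 and sum to 1, "
                         f"got {dict(artifact_mix)}")
    for k in kinds:
        if k != "none" and k not in _WAVEFORMS:
            raise ValueError(f"unknown artifact kind {k!r} in mix")
    amps = dict(DEFAULT_AMPLITUDES)
    if amplitudes:
        amps.update(amplitudes)
    rng = np.random.default_rng(seed)
    drawn = rng.choice(len(kinds), size=n_trials, p=probs)
    clean, noisy, specs = [], [], []
    for i in range(n_trials):
        kind = kinds[drawn[i]]
        trial_seed = int(rng.integers(0, 2 ** 31))
        art_seed = int(rng.integers(0, 2 ** 31))
        t = generate_clean_trial(config, seed=trial_seed)
        spec = ArtifactSpec(kind=kind, amplitude=amps.get(kind, 0.0), seed=art_seed)
        clean.append(t)
        noisy.append(inject(t, spec))
        specs.append(spec)
    return PairedDataset(clean=clean, noisy=noisy, specs=specs, seed=seed,
                         config=config)
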
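"""Simulator calibration and artifact-injector contracts."""

import numpy as np
import pytest
from scipy import signal as sps

from eegdenoise.preprocess import bandpass_filter
from eegdenoise.sample_entropy import channel_entropies
from eegdenoise.setet_norm import flag_segments
from eegdenoise.synth import (ArtifactSpec, CleanEEGConfig, blink_waveform,
                              emg_waveform, generate_clean_trial,
                              heartbeat_waveform, inject, inject_blink,
                              inject_emg, inject_heartbeat, inject_line_noise,
                              make_paired_dataset)
from eegdenoise.types import RawRecording


class TestCleanTrials:
    def test_energy_and_entropy_regimes_over_seeds(self):
        # spot-check the study-condition invariants on a modest seed sample;
        # the full 50-seed sweep runs in the acceptance suite
        for seed in range(12):
            t = generate_clean_trial(seed=seed)
            assert 20.0 <= np.mean(np.abs(t.data)) <= 30.0
            se = channel_entropies(t)
            assert np.all(se > 0.3) and np.all(se <= 1.5)

    def test_seed_reproducibility(self):
        a = generate_clean_trial(seed=42)
        b = generate_clean_trial(seed=42)
        assert np.array_equal(a.data, b.data)
        c = generate_clean_trial(seed=43)
        assert not np.array_equal(a.data, c.data)

    def test_custom_geometry(self):
        cfg = CleanEEGConfig(n_channels=8, n_samples=100)
        t = generate_clean_trial(cfg, seed=0)
        assert t.data.shape == (8, 100)


class TestBlink:
    def test_zero_amplitude_is_identity(self, clean_trial):
        spec = ArtifactSpec(kind="blink", amplitude=0.0, seed=3)
        noisy = inject_blink(clean_trial, spec)
        assert np.array_equal(noisy.data, clean_trial.data)

    def test_additivity(self, clean_trial):
        spec = ArtifactSpec(kind="blink", amplitude=600.0, seed=3)
        noisy = inject_blink(clean_trial, spec)
        wave = blink_waveform(clean_trial, spec)
        diff = noisy.data - clean_trial.data
        assert np.allclose(diff, wave, atol=1e-9)
        assert np.all(diff[np.abs(wave) == 0] == 0)

    def test_spectral_centroid_below_5hz(self, clean_trial):
        spec = ArtifactSpec(kind="blink", amplitude=600.0, seed=3)
        wave = blink_waveform(clean_trial, spec)[0]
        freqs, psd = sps.periodogram(wave, fs=clean_trial.fs)
        centroid = (freqs * psd).sum() / psd.sum()
        assert centroid < 5.0

    def test_triggers_setet_flags(self, clean_trial):
        noisy = inject_blink(clean_trial)
        mask = flag_segments(noisy)
        assert mask.flags[:4].any()

    def test_frontal_channels_required(self, clean_trial):
        bare = type(clean_trial)(clean_trial.data[:4], clean_trial.fs,
                                 ("P3", "P4", "O1", "O2"))
        with pytest.raises(ValueError):
            inject_blink(bare)


class TestEmg:
    def test_power_concentrated_above_30hz(self, clean_trial):
        spec = ArtifactSpec(kind="emg", amplitude=40.0, seed=5)
        wave = emg_waveform(clean_trial, spec)
        active = wave[np.abs(wave).sum(axis=1) > 0]
        freqs, psd = sps.periodogram(active, fs=clean_trial.fs, axis=-1)
        frac = psd[:, freqs > 30].sum() / psd.sum()
        assert frac >= 0.9

    def test_zero_amplitude_identity(self, clean_trial):
        spec = ArtifactSpec(kind="emg", amplitude=0.0, seed=5)
        assert np.array_equal(inject_emg(clean_trial, spec).data, clean_trial.data)

    def test_confined_to_window(self, clean_trial):
        spec = ArtifactSpec(kind="emg", amplitude=40.0, onset=50, duration=60, seed=5)
        noisy = inject_emg(clean_trial, spec)
        diff = noisy.data - clean_trial.data
        assert np.all(diff[:, :50] == 0) and np.all(diff[:, 110:] == 0)

    def test_window_out_of_range_rejected(self, clean_trial):
        spec = ArtifactSpec(kind="emg", amplitude=40.0, onset=180, duration=40)
        with pytest.raises(ValueError):
            inject_emg(clean_trial, spec)


class TestLineNoise:
    def test_difference_is_pure_sinusoid(self, clean_trial):
        spec = ArtifactSpec(kind="line", amplitude=10.0, seed=2)
        noisy = inject_line_noise(clean_trial, spec)
        diff = noisy.data - clean_trial.data
        freqs, psd = sps.periodogram(diff[0], fs=clean_trial.fs)
        assert freqs[np.argmax(psd)] == pytest.approx(50.0, abs=1.0)
        assert np.allclose(diff, diff[0])  # common phase across channels

    def test_bandpass_removes_it(self, clean_trial):
        spec = ArtifactSpec(kind="line", amplitude=10.0, seed=2)
        noisy = inject_line_noise(clean_trial, spec)
        rec = RawRecording(np.tile(noisy.data, (1, 5)), noisy.fs,
                           noisy.channel_labels)
        filt = bandpass_filter(rec)
        diff_power = lambda d: sps.periodogram(d, fs=200.0)[1][
            sps.periodogram(d, fs=200.0)[0] >= 49.5].max()
        before = diff_power(rec.data[0])
        after = diff_power(filt.data[0])
        assert after < before * 10 ** (-20 / 10)

    def test_zero_amplitude_identity(self, clean_trial):
        spec = ArtifactSpec(kind="line", amplitude=0.0, seed=2)
        assert np.array_equal(inject_line_noise(clean_trial, spec).data,
                              clean_trial.data)


class TestHeartbeat:
    def test_one_event_per_second_at_1hz(self, clean_trial):
        spec = ArtifactSpec(kind="heartbeat", amplitude=30.0, freq=1.0,
                            onset=50, seed=0)
        wave = heartbeat_waveform(clean_trial, spec)
        ch = wave[np.abs(wave).sum(axis=1) > 0][0]
        peaks, _ = sps.find_peaks(np.abs(ch), height=25.0)
        assert len(peaks) == 1

    def test_events_equally_spaced(self, clean_trial):
        spec = ArtifactSpec(kind="heartbeat", amplitude=30.0, freq=4.0,
                            onset=10, duration=4, seed=0)
        wave = heartbeat_waveform(clean_trial, spec)
        ch = wave[np.abs(wave).sum(axis=1) > 0][0]
        peaks, _ = sps.find_peaks(ch, height=25.0)
        gaps = np.diff(peaks)
        assert np.all(np.abs(gaps - 50) <= 1)

    def test_zero_amplitude_identity(self, clean_trial):
        spec = ArtifactSpec(kind="heartbeat", amplitude=0.0, seed=0)
        assert np.array_equal(inject_heartbeat(clean_trial, spec).data,
                              clean_trial.data)


class TestPairedDataset:
    def test_reproducible_from_seed(self):
        mix = {"blink": 0.5, "none": 0.5}
        a = make_paired_dataset(20, mix, seed=9)
        b = make_paired_dataset(20, mix, seed=9)
        for ta, tb in zip(a.noisy, b.noisy):
            assert np.array_equal(ta.data, tb.data)

    def test_none_mix_gives_equal_pairs(self):
        ds = make_paired_dataset(10, {"none": 1.0}, seed=3)
        for c, n in zip(ds.clean, ds.noisy):
            assert np.array_equal(c.data, n.data)

    def test_noisy_minus_clean_is_annotated_artifact(self):
        ds = make_paired_dataset(20, {"blink": 0.4, "emg": 0.3, "none": 0.3}, seed=4)
        for c, n, spec in zip(ds.clean, ds.noisy, ds.specs):
            diff = n.data - c.data
            if spec.kind == "none":
                assert np.all(diff == 0)
            else:
                assert np.abs(diff).max() > 0

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            make_paired_dataset(5, {"blink": 0.7, "none": 0.5}, seed=0)
        with pytest.raises(ValueError):
            make_paired_dataset(5, {"sneeze": 1.0}, seed=0)

    def test_kind_counts_within_multinomial_bounds(self):
        # n=100, p=0.5: the 99% two-sided binomial band is roughly [37, 63]
        counts = []
        for seed in range(5):
            ds = make_paired_dataset(100, {"blink": 0.5, "none": 0.5}, seed=seed)
            counts.append(sum(s.kind == "blink" for s in ds.specs))
        assert all(37 <= c <= 63 for c in counts)
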
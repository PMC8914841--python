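"""SETET screen: threshold selection, flagging, coefficient, exact inversion."""

import numpy as np
import pytest

from eegdenoise.sample_entropy import SampEnParams, sample_entropy
from eegdenoise.setet_norm import (EntropyThresholdInputs, SetetConfig,
                                   compute_normalization_coefficient,
                                   denormalize, flag_segments, normalize,
                                   segment_mean_energy, segment_slices,
                                   select_entropy_threshold, setet_normalize)
from eegdenoise.synth import ArtifactSpec, blink_waveform, generate_clean_trial
from eegdenoise.types import Trial


class TestEntropyThreshold:
    def test_all_equal_returns_frontal_mean(self):
        k = select_entropy_threshold(EntropyThresholdInputs(0.5, 0.5, 0.5, delta=0.2))
        assert k == 0.5

    def test_spread_above_delta_uses_midpoint(self):
        k = select_entropy_threshold(EntropyThresholdInputs(0.4, 0.3, 0.9, delta=0.1))
        assert k == pytest.approx(0.65)

    def test_spread_within_delta_uses_frontal(self):
        k = select_entropy_threshold(EntropyThresholdInputs(0.50, 0.48, 0.52, delta=0.1))
        assert k == 0.48


class TestSegmentEnergy:
    def test_constant_ones(self):
        assert np.allclose(segment_mean_energy(np.ones(20), 4), 1.0)

    def test_block_means_of_absolute_values(self):
        x = np.array([0, 0, 0, 0, -10, 10, -10, 10], float)
        assert np.allclose(segment_mean_energy(x, 2), [0.0, 10.0])

    def test_zeros(self):
        assert np.allclose(segment_mean_energy(np.zeros(16), 4), 0.0)

    def test_too_many_segments_rejected(self):
        with pytest.raises(ValueError):
            segment_mean_energy(np.ones(5), 6)

    def test_last_segment_absorbs_remainder(self):
        slices = segment_slices(23, 4)
        assert slices[-1] == slice(15, 23)
        assert sum(s.stop - s.start for s in slices) == 23


def naive_flags(trial, config, params):
    """Independent double-loop recomputation of the two-stage screen."""
    flags = np.zeros((trial.n_channels, config.n_segments), dtype=bool)
    for c in range(trial.n_channels):
        se = sample_entropy(trial.data[c], params)
        for j, s in enumerate(segment_slices(trial.n_samples, config.n_segments)):
            energy = np.mean(np.abs(trial.data[c, s]))
            flags[c, j] = (se < config.k) and (energy > config.e)
    return flags


class TestFlagSegments:
    def test_matches_naive_recomputation(self, rng):
        for _ in range(5):
            t = Trial(rng.normal(0, 30, (4, 40)), 200.0, ("a", "b", "c", "d"))
            cfg = SetetConfig(k=0.8, e=25.0, n_segments=5)
            got = flag_segments(t, cfg)
            assert np.array_equal(got.flags, naive_flags(t, cfg, SampEnParams()))

    def test_clean_trial_unflagged(self):
        t = generate_clean_trial(seed=3)
        assert not flag_segments(t).flags.any()

    def test_blink_flags_only_its_segment(self):
        t = generate_clean_trial(seed=3)
        # large slow transient confined to segments 2-3 of Fp1/Fp2
        spec = ArtifactSpec(kind="blink", amplitude=900.0, onset=40, duration=40,
                            channels=("Fp1", "Fp2"))
        noisy = t.with_data(t.data + blink_waveform(t, spec))
        mask = flag_segments(noisy)
        assert mask.flags[:2, 2:4].any()
        assert not mask.flags[:, 6:].any()
        assert not mask.flags[4:].any()

    def test_constant_huge_channel_fully_flagged(self):
        data = np.vstack([np.full(40, 200.0), np.zeros(40), np.ones(40)])
        t = Trial(data, 200.0, ("a", "b", "c"))
        mask = flag_segments(t, SetetConfig(k=0.3, e=50.0, n_segments=4))
        assert mask.flags[0].all()
        assert not mask.flags[1:].any()


class TestNormalizationCoefficient:
    def test_no_flags_plain_max_abs(self):
        data = np.zeros((2, 20))
        data[1, 7] = -37.5
        t = Trial(data + 0.1, 200.0, ("a", "b"))
        mask = flag_segments(t, SetetConfig(k=0.001, e=1e9, n_segments=4))
        assert compute_normalization_coefficient(t, mask) == pytest.approx(
            np.abs(t.data).max())

    def test_flagged_spike_excluded(self):
        t = generate_clean_trial(seed=9)
        spec = ArtifactSpec(kind="blink", amplitude=900.0, onset=40, duration=40,
                            channels=("Fp1",))
        noisy = t.with_data(t.data + blink_waveform(t, spec))
        mask = flag_segments(noisy)
        m = compute_normalization_coefficient(noisy, mask)
        assert m < 300  # spike peak ~900 is excluded
        keep = np.abs(noisy.data) <= m
        assert keep.sum() > 0.9 * noisy.data.size

    def test_all_zero_trial_fallback_one(self):
        t = Trial(np.zeros((2, 20)), 200.0, ("a", "b"))
        mask = flag_segments(t)
        assert compute_normalization_coefficient(t, mask) == 1.0

    def test_all_flagged_falls_back_to_global_max(self):
        data = np.full((2, 20), 100.0)
        data[0, 0] = 400.0
        t = Trial(data, 200.0, ("a", "b"))
        mask = flag_segments(t, SetetConfig(k=0.5, e=50.0, n_segments=4))
        assert mask.flags.all()
        assert compute_normalization_coefficient(t, mask) == 400.0


class TestNormalizeRoundTrip:
    def test_unit_coefficient_is_identity(self, small_trial):
        res = normalize(small_trial, 1.0)
        assert np.array_equal(res.S.data, small_trial.data)

    def test_elementwise_division(self):
        data = np.tile([-10.0, 5.0], (2, 8))
        t = Trial(data, 200.0, ("a", "b"))
        res = normalize(t, 5.0)
        assert set(np.unique(res.S.data)) == {-2.0, 1.0}

    def test_nonpositive_coefficient_rejected(self, small_trial):
        for m in (0.0, -1.0):
            with pytest.raises(ValueError):
                normalize(small_trial, m)

    def test_round_trip_identity(self, rng):
        for _ in range(10):
            t = Trial(rng.normal(0, 50, (3, 32)), 200.0, ("a", "b", "c"))
            res = setet_normalize(t)
            back = denormalize(res)
            assert np.max(np.abs(back.data - t.data)) < 1e-10 * res.m

    def test_unflagged_samples_bounded_by_one(self):
        t = generate_clean_trial(seed=4)
        res = setet_normalize(t)
        assert not res.mask.flags.any()
        assert np.abs(res.S.data).max() <= 1.0 + 1e-12


def test_fully_flagged_blink_never_increases_m(rng):
    """Excluding a flagged artifact keeps m at the clean trial's scale."""
    t = generate_clean_trial(seed=17)
    m_clean = compute_normalization_coefficient(t, flag_segments(t))
    n_checked = 0
    for i in range(100):
        # segment-aligned placement so every touched segment carries real energy
        onset = 20 * int(rng.integers(0, 6))
        dur = 20 * int(rng.integers(4, 6))
        spec = ArtifactSpec(kind="blink", amplitude=float(rng.uniform(800, 1200)),
                            onset=onset, duration=dur,
                            channels=("Fp1", "Fp2"), seed=i)
        noisy = t.with_data(t.data + blink_waveform(t, spec))
        mask = flag_segments(noisy)
        wave = blink_waveform(t, spec)
        touched = np.abs(wave) > 1e-9
        slices = segment_slices(t.n_samples, mask.n_segments)
        fully_flagged = all(
            mask.flags[c, j]
            for c in range(t.n_channels)
            for j, s in enumerate(slices)
            if touched[c, s].any()
        )
        if fully_flagged:
            n_checked += 1
            assert compute_normalization_coefficient(noisy, mask) <= m_clean
    assert n_checked >= 50  # the large blinks used here are reliably screened
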
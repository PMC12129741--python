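"""Inertial speed, condition windows, binning and smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurokinetics.io import InertialTrace, InjectionEvent, SpeedSeries
from neurokinetics.preprocess import (
    WindowError,
    bin_spike_counts,
    compute_inertial_speed,
    downsample_lfp,
    frame_average_speed,
    resolve_condition_windows,
    smooth_counts,
)


class TestInertialSpeed:
    def test_constant_channels_give_zero_speed(self):
        imu = InertialTrace(np.full((1000, 6), 3.7))
        speed = compute_inertial_speed(imu)
        assert speed.values.shape == (999,)
        assert np.all(speed.values == 0)

    def test_single_ramp_channel_gives_slope_over_six(self):
        data = np.zeros((500, 6))
        data[:, 2] = 0.6 * np.arange(500)
        speed = compute_inertial_speed(imu := InertialTrace(data))
        np.testing.assert_allclose(speed.values, 0.6 / 6.0)

    def test_random_walk_mean_matches_folded_normal(self):
        # mean |increment| of a random walk with step SD sigma is sigma*sqrt(2/pi)
        rng = np.random.default_rng(42)
        sigma = 0.8
        data = np.cumsum(sigma * rng.standard_normal((10**6, 6)), axis=0)
        speed = compute_inertial_speed(InertialTrace(data))
        expected = sigma * np.sqrt(2.0 / np.pi)
        assert speed.values.mean() == pytest.approx(expected, rel=0.02)

    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((200, 6))
        s1 = compute_inertial_speed(InertialTrace(data)).values
        s2 = compute_inertial_speed(InertialTrace(data + [1, -2, 3, 0, 5, -7])).values
        np.testing.assert_allclose(s1, s2)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            compute_inertial_speed(InertialTrace(np.zeros((1, 6))))


class TestConditionWindows:
    def test_ld_then_ketamine_window(self):
        events = [InjectionEvent("L-DOPA", 30.0), InjectionEvent("ketamine", 90.0)]
        wins = {w.label: w for w in resolve_condition_windows(events, 120.0)}
        assert (wins["LD->K"].start_min, wins["LD->K"].end_min) == (95.0, 115.0)
        assert (wins["BL"].start_min, wins["BL"].end_min) == (5.0, 25.0)

    def test_vehicle_then_ketamine_windows(self):
        # ketamine 30 min after vehicle: V = [5, 25], K = [35, 55] post-vehicle
        events = [InjectionEvent("vehicle", 30.0), InjectionEvent("ketamine", 60.0)]
        wins = {w.label: w for w in resolve_condition_windows(events, 90.0)}
        assert (wins["V"].start_min, wins["V"].end_min) == (35.0, 55.0)
        assert (wins["K"].start_min, wins["K"].end_min) == (65.0, 85.0)

    def test_ld_window_is_65_to_85_post_injection(self):
        events = [InjectionEvent("L-DOPA", 0.0), InjectionEvent("vehicle", 60.0)]
        wins = {w.label: w for w in resolve_condition_windows(events, 90.0)}
        assert (wins["LD"].start_min, wins["LD"].end_min) == (65.0, 85.0)

    def test_baseline_clipped_with_warning(self):
        events = [InjectionEvent("vehicle", 10.0), InjectionEvent("ketamine", 40.0)]
        with pytest.warns(UserWarning, match="clipped"):
            wins = {w.label: w for w in resolve_condition_windows(events, 70.0)}
        assert wins["BL"].start_min == 0.0
        assert wins["BL"].end_min == 5.0

    def test_short_session_names_offending_window(self):
        events = [InjectionEvent("L-DOPA", 30.0), InjectionEvent("ketamine", 90.0)]
        with pytest.raises(WindowError, match="LD->K"):
            resolve_condition_windows(events, 100.0)

    def test_unrecognised_sequence_rejected(self):
        events = [InjectionEvent("ketamine", 10.0), InjectionEvent("vehicle", 40.0)]
        with pytest.raises(WindowError, match="session type"):
            resolve_condition_windows(events, 90.0)

    def test_default_windows_are_twenty_minutes(self):
        events = [InjectionEvent("L-DOPA", 30.0), InjectionEvent("ketamine", 90.0)]
        for w in resolve_condition_windows(events, 120.0):
            assert w.end_min - w.start_min == pytest.approx(20.0)


class TestBinning:
    def test_hand_counted_bins(self):
        counts = bin_spike_counts(np.array([0.001, 0.004, 0.007]), 0.005, (0.0, 0.015))
        np.testing.assert_array_equal(counts, [2, 1, 0])

    def test_empty_train_gives_zeros(self):
        counts = bin_spike_counts(np.array([]), 0.005, (0.0, 0.1))
        assert counts.shape == (20,)
        assert counts.sum() == 0

    def test_count_conservation_against_brute_force(self):
        rng = np.random.default_rng(3)
        spikes = np.sort(rng.uniform(0, 10, 500))
        window = (2.0, 8.0)
        counts = bin_spike_counts(spikes, 0.05, window)
        direct = np.count_nonzero((spikes >= window[0]) & (spikes < window[1]))
        assert counts.sum() == direct


class TestSmoothing:
    def test_constant_preserved(self):
        out = smooth_counts(np.full(100, 4.0), 50.0)
        np.testing.assert_allclose(out, 4.0)

    def test_impulse_becomes_plateau(self):
        x = np.zeros(100)
        x[50] = 1.0
        out = smooth_counts(x, 50.0)  # 10 bins of 5 ms
        assert out[50] == pytest.approx(0.1)
        assert np.isclose(out, 0.1).sum() == 10

    @given(st.integers(min_value=1, max_value=40), st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_bruteforce_shrinking_average(self, w_bins, seed):
        rng = np.random.default_rng(seed)
        x = rng.poisson(2.0, size=60).astype(float)
        out = smooth_counts(x, w_bins * 5.0)
        left = w_bins // 2
        right = w_bins - 1 - left
        expected = np.array([
            x[max(i - left, 0): min(i + right + 1, x.size)].mean()
            for i in range(x.size)
        ])
        np.testing.assert_allclose(out, expected)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            smooth_counts(np.zeros(10), 500.0)


class TestLfpDownsampling:
    def test_tone_survives_decimation(self):
        fs_in = 2500.0
        t = np.arange(int(4 * fs_in)) / fs_in
        x = np.sin(2 * np.pi * 40 * t)
        y = downsample_lfp(x, fs_in, 500.0)
        assert y.size == x.size // 5
        t_out = np.arange(y.size) / 500.0
        # ignore filter edge transients
        core = slice(200, -200)
        np.testing.assert_allclose(
            y[core], np.sin(2 * np.pi * 40 * t_out)[core], atol=0.02
        )

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError, match="factor"):
            downsample_lfp(np.zeros(1000), 1100.0, 500.0)


class TestFrameAverage:
    def test_overlapping_frames_average_correct_samples(self):
        # speed of 1 in the first second, 3 afterwards; 1 s frames, 0.5 s hop
        v = np.concatenate([np.ones(200), 3 * np.ones(600)])
        sp = SpeedSeries(v, fs=200.0)
        out = frame_average_speed(sp, (0.0, 4.0))
        assert out[0] == pytest.approx(1.0)  # [0, 1) s
        assert out[1] == pytest.approx(2.0)  # [0.5, 1.5) s straddles the step
        assert out[2] == pytest.approx(3.0)
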
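"""Waveform features, autocorrelograms, LvR, cell typing, inclusion, layers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurokinetics import units as um
from neurokinetics.preprocess import ConditionWindow

FS = 30000.0


def biphasic(trough=-80.0, peak=40.0, trough_sigma_ms=0.15, peak_sigma_ms=0.3,
             n=64, fs=FS):
    t = np.arange(n) / fs * 1000.0  # ms
    t0 = n / fs * 1000 * 0.35
    t1 = t0 + 3.5 * trough_sigma_ms + 1.5 * peak_sigma_ms
    return (trough * np.exp(-((t - t0) ** 2) / (2 * trough_sigma_ms**2))
            + peak * np.exp(-((t - t1) ** 2) / (2 * peak_sigma_ms**2)))


class TestWaveformFeatures:
    def test_equal_peak_and_trough_gives_ratio_one(self):
        f = um.extract_waveform_features(biphasic(trough=-60, peak=60), FS)
        assert f.peak_trough_ratio == pytest.approx(1.0, abs=0.01)

    def test_half_amplitude_peak_gives_ratio_half(self):
        f = um.extract_waveform_features(biphasic(trough=-80, peak=40), FS)
        assert f.peak_trough_ratio == pytest.approx(0.5, abs=0.01)

    def test_width_scales_with_planted_factor(self):
        narrow = um.extract_waveform_features(biphasic(trough_sigma_ms=0.1), FS)
        wide = um.extract_waveform_features(biphasic(trough_sigma_ms=0.2), FS)
        # FWHM of a Gaussian deflection is proportional to sigma
        assert wide.half_width_ms / narrow.half_width_ms == pytest.approx(2.0, abs=0.15)

    def test_monophasic_waveform_rejected(self):
        t = np.arange(64) / FS * 1000
        mono = -80.0 * np.exp(-((t - 0.7) ** 2) / (2 * 0.15**2))
        with pytest.raises(um.WaveformError):
            um.extract_waveform_features(mono, FS)

    def test_largest_amplitude_channel_selected(self):
        w = np.zeros((64, 4))
        w[:, 2] = biphasic()
        w[:, 0] = 0.1 * biphasic(trough=-80, peak=8)  # different ratio, smaller
        f = um.extract_waveform_features(w, FS)
        assert f.peak_trough_ratio == pytest.approx(0.5, abs=0.01)


class TestAutocorrelogram:
    def test_periodic_train_peaks_at_period(self):
        spikes = np.arange(0, 60, 0.1)  # 100 ms period
        acg = um.compute_autocorrelogram(spikes, bin_ms=1.0, max_lag_ms=250.0)
        assert acg.peak_lag_ms == pytest.approx(100.0, abs=1.0)
        top = np.sort(acg.counts)[-2:].min()
        lag_bins = acg.lags_ms[acg.counts >= top]
        assert np.any(np.abs(lag_bins - 100.0) <= 1.0)
        assert np.any(np.abs(lag_bins - 200.0) <= 1.0)

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(9)
        spikes = np.sort(rng.uniform(0, 5, 200))
        acg = um.compute_autocorrelogram(spikes, bin_ms=1.0, max_lag_ms=50.0)
        diffs = spikes[None, :] - spikes[:, None]
        lags = diffs[(diffs > 0) & (diffs <= 0.05)]
        brute, _ = np.histogram(lags, bins=np.arange(51) / 1000.0)
        np.testing.assert_array_equal(acg.counts, brute)

    def test_poisson_acg_flat(self):
        rng = np.random.default_rng(10)
        spikes = np.cumsum(rng.exponential(0.05, 20000))
        acg = um.compute_autocorrelogram(spikes, bin_ms=1.0, max_lag_ms=50.0)
        counts = acg.counts.astype(float)
        assert counts.std() / counts.mean() < 0.1

    def test_mirrored_view_symmetric(self):
        rng = np.random.default_rng(11)
        spikes = np.sort(rng.uniform(0, 10, 300))
        acg = um.compute_autocorrelogram(spikes)
        lags, counts = acg.mirrored()
        np.testing.assert_array_equal(counts, counts[::-1])
        np.testing.assert_allclose(lags, -lags[::-1])


class TestLocalVariance:
    def test_regular_train_is_exactly_zero(self):
        assert um.local_variance(np.arange(200) * 0.1) == 0.0

    def test_poisson_mean_near_one(self):
        rng = np.random.default_rng(12)
        lvs = [
            um.local_variance(rng.exponential(0.1, 10**4), from_isis=True)
            for _ in range(100)
        ]
        assert np.mean(lvs) == pytest.approx(1.0, abs=0.02)

    def test_alternating_isis_match_hand_computation(self):
        # each consecutive pair (10, 100) ms contributes 3*(1 - 4*1000/110^2)
        isis = np.tile([0.01, 0.1], 600)
        expected = 3.0 * (1.0 - 4.0 * 1000.0 / 110.0**2)
        assert um.local_variance(isis, from_isis=True) == pytest.approx(expected, abs=1e-6)

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_rescale_invariance_at_r_zero(self, factor):
        rng = np.random.default_rng(13)
        isis = rng.gamma(0.5, 0.1, 500)
        lv1 = um.local_variance(isis, from_isis=True)
        lv2 = um.local_variance(isis * factor, from_isis=True)
        assert lv2 == pytest.approx(lv1, rel=1e-9)

    def test_refractoriness_breaks_rescale_invariance(self):
        rng = np.random.default_rng(14)
        isis = rng.gamma(0.5, 0.1, 500)
        lv1 = um.local_variance(isis, refractoriness_s=0.005, from_isis=True)
        lv2 = um.local_variance(isis * 10, refractoriness_s=0.005, from_isis=True)
        assert abs(lv1 - lv2) > 1e-3

    def test_extreme_alternation_approaches_three(self):
        isis = np.tile([1e-6, 1.0], 600)
        lv = um.local_variance(isis, from_isis=True)
        assert 2.99 < lv < 3.0

    def test_nonpositive_isi_rejected(self):
        with pytest.raises(ValueError):
            um.local_variance(np.array([0.1, 0.0, 0.2]), from_isis=True)


class TestClassification:
    def test_planted_populations_recovered(self, population_session):
        session, truth, _, _ = population_session
        feats, lags, rates, classes = [], [], [], []
        for u, c in zip(session.units, truth.unit_classes):
            feats.append(um.extract_waveform_features(u.mean_waveform, u.waveform_fs))
            lags.append(um.compute_autocorrelogram(u.spike_times).peak_lag_ms)
            rates.append(u.n_spikes / session.duration_s)
            classes.append(c)
        labels = um.classify_cell_types(feats, np.array(lags), np.array(rates))
        agree = np.mean([lab.label == c for lab, c in zip(labels, classes)])
        assert agree >= 0.95

    def test_rate_ordering_matches_phenomenology(self, population_session):
        session, truth, _, _ = population_session
        rates = {}
        for u, c in zip(session.units, truth.unit_classes):
            rates.setdefault(c, []).append(u.n_spikes / session.duration_s)
        assert np.mean(rates["IN"]) > np.mean(rates["HFWW"]) > np.mean(rates["LFWW"])

    def test_identical_features_raise_degenerate_error(self):
        f = um.extract_waveform_features(biphasic(), FS)
        with pytest.raises(um.DegenerateFeaturesError):
            um.classify_cell_types([f] * 10, np.ones(10), np.ones(10))

    def test_permutation_invariance(self, population_session):
        session, truth, _, _ = population_session
        feats, lags, rates = [], [], []
        for u in session.units[:60]:
            feats.append(um.extract_waveform_features(u.mean_waveform, u.waveform_fs))
            lags.append(um.compute_autocorrelogram(u.spike_times[:2000]).peak_lag_ms)
            rates.append(u.n_spikes / session.duration_s)
        lags, rates = np.array(lags), np.array(rates)
        labels = um.classify_cell_types(feats, lags, rates)
        perm = np.random.default_rng(15).permutation(60)
        plabels = um.classify_cell_types(
            [feats[i] for i in perm], lags[perm], rates[perm]
        )
        for k, i in enumerate(perm):
            assert plabels[k].label == labels[i].label


class TestInclusion:
    WINDOWS = [ConditionWindow("BL", 0.0, 20.0)]

    def test_clean_unit_included(self):
        rng = np.random.default_rng(16)
        isis = 0.002 + rng.exponential(1.0, 1500)
        spikes = np.cumsum(isis)
        ok, reasons = um.unit_inclusion(spikes, self.WINDOWS)
        assert ok and reasons == []

    def test_low_rate_unit_excluded(self):
        spikes = np.arange(0, 1200, 25.0)  # 0.04 Hz
        ok, reasons = um.unit_inclusion(spikes, self.WINDOWS)
        assert not ok and "rate" in reasons

    def test_refractory_contamination_excluded(self):
        rng = np.random.default_rng(17)
        isis = 0.003 + rng.exponential(0.5, 2000)
        contaminated = isis.copy()
        contaminated[:: 20] = 0.001  # 5% sub-refractory intervals
        spikes = np.cumsum(contaminated)
        ok, reasons = um.unit_inclusion(spikes, self.WINDOWS)
        assert not ok and "refractory" in reasons


class TestLayers:
    @pytest.mark.parametrize(
        "depth,layer",
        [(500, "L23"), (749.9, "L23"), (750, "L5"), (1399, "L5"),
         (1400, "L6"), (2100, "L6"), (2200, "out-of-range")],
    )
    def test_depth_bins(self, depth, layer):
        assert um.assign_layer(depth) == layer

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            um.assign_layer(-10.0)
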
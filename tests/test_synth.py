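"""Generator contracts: determinism, planted-parameter recovery hooks,
refractoriness and configuration validation."""

import numpy as np
import pytest

from neurokinetics import synth
from neurokinetics.preprocess import compute_inertial_speed
from neurokinetics.units import local_variance


def _tiny_config(**kw):
    base = dict(
        seed=11,
        duration_min=2.0,
        injection_schedule=[("vehicle", 0.0)],
        movement={"V": synth.MovementSpec(1.0, 0.5)},
        oscillations={},
        population={},
    )
    base.update(kw)
    return synth.SynthConfig(**base)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = synth.default_config(seed=9, session_type="V->K", duration_min=3.0,
                                   schedule=[("vehicle", 1.0), ("ketamine", 2.0)])
        s1, _ = synth.generate_session(cfg)
        s2, _ = synth.generate_session(cfg)
        np.testing.assert_array_equal(s1.lfp, s2.lfp)
        np.testing.assert_array_equal(s1.imu.data, s2.imu.data)
        for u1, u2 in zip(s1.units, s2.units):
            np.testing.assert_array_equal(u1.spike_times, u2.spike_times)
            np.testing.assert_array_equal(u1.mean_waveform, u2.mean_waveform)

    def test_different_seeds_differ(self):
        cfg1 = _tiny_config(seed=1)
        cfg2 = _tiny_config(seed=2)
        s1, _ = synth.generate_session(cfg1)
        s2, _ = synth.generate_session(cfg2)
        assert not np.array_equal(s1.lfp, s2.lfp)


class TestNullModel:
    def test_zero_config_plants_nothing(self):
        cfg = _tiny_config(movement={"V": synth.MovementSpec(0.0, 0.0)})
        session, truth = synth.generate_session(cfg)
        # flat movement: latent speed identically zero, channels constant
        assert np.all(truth.latent_speed.values == 0)
        assert np.all(compute_inertial_speed(session.imu).values == 0)
        assert truth.pair_loadings == {}
        # LFP is pure 1/f noise with the configured RMS
        assert session.lfp.std() == pytest.approx(cfg.background_rms_uv, rel=0.01)


class TestMovement:
    def test_doubled_mean_speed_recovers_ratio_two(self):
        lo = _tiny_config(seed=21, duration_min=10.0,
                          movement={"V": synth.MovementSpec(1.0, 0.3)})
        hi = _tiny_config(seed=21, duration_min=10.0,
                          movement={"V": synth.MovementSpec(2.0, 0.3)})
        m = []
        for cfg in (lo, hi):
            session, _ = synth.generate_session(cfg)
            m.append(compute_inertial_speed(session.imu).values.mean())
        assert m[1] / m[0] == pytest.approx(2.0, rel=0.05)

    def test_variability_monotone_in_planted_sd(self):
        sds = [0.1, 0.4, 0.8]
        out = []
        for sd in sds:
            cfg = _tiny_config(seed=33, duration_min=10.0,
                               movement={"V": synth.MovementSpec(2.0, sd)})
            session, _ = synth.generate_session(cfg)
            # SD of the frame-averaged speed isolates the latent variability
            sp = compute_inertial_speed(session.imu).values
            frames = sp[: sp.size // 200 * 200].reshape(-1, 200).mean(axis=1)
            out.append(frames.std())
        assert out[0] < out[1] < out[2]

    def test_negative_sd_rejected(self):
        with pytest.raises(synth.SynthConfigError):
            synth.MovementSpec(1.0, -0.1)


class TestSpikes:
    def test_refractory_period_respected(self, population_session):
        session, _, _, _ = population_session
        for u in session.units:
            if u.n_spikes > 2:
                assert np.diff(u.spike_times).min() >= 0.002 - 1e-12

    def test_lfww_regime_is_bursty(self, population_session):
        session, truth, _, _ = population_session
        lvs = [
            local_variance(u.spike_times)
            for u, c in zip(session.units, truth.unit_classes)
            if c == "LFWW" and u.n_spikes > 50
        ]
        assert np.mean(lvs) > 1.0
        assert np.mean(np.array(lvs) > 1.0) > 0.9

    def test_rate_ceiling_enforced(self):
        pop = {
            "HFWW": synth.CellClassSpec(
                n=1, base_rate_hz=50.0, gains={"V": 500.0}, gamma_shape=1.0,
                half_width_ms=0.3, peak_trough_ratio=0.7, peak_width_factor=2.0,
            )
        }
        cfg = _tiny_config(population=pop)
        with pytest.raises(synth.SynthConfigError, match="ceiling"):
            synth.generate_session(cfg)

    def test_zero_gain_units_uncoupled(self):
        pop = {
            "HFWW": synth.CellClassSpec(
                n=5, base_rate_hz=8.0, gains={"V": 0.0}, gamma_shape=1.0,
                half_width_ms=0.3, peak_trough_ratio=0.7, peak_width_factor=2.0,
            )
        }
        cfg = _tiny_config(seed=8, duration_min=10.0, population=pop)
        session, truth = synth.generate_session(cfg)
        speed = truth.latent_speed.values
        for u in session.units:
            counts = np.histogram(u.spike_times, bins=np.arange(0, 601, 1.0))[0]
            s1 = speed[: 600 * 200].reshape(600, 200).mean(axis=1)
            r = np.corrcoef(counts, s1)[0, 1]
            assert abs(r) < 0.12  # null fluctuation at n=600 bins


class TestConfigValidation:
    def test_schedule_outside_duration_rejected(self):
        cfg = _tiny_config(injection_schedule=[("vehicle", 5.0)])
        with pytest.raises(synth.SynthConfigError, match="outside"):
            cfg.validate()

    def test_pair_structure_requires_units(self):
        cfg = _tiny_config(
            pair_structure=synth.PairStructureSpec(2, {"V": np.zeros((0, 2))})
        )
        with pytest.raises(synth.SynthConfigError, match="zero units"):
            cfg.validate()

    def test_loading_shape_mismatch_rejected(self):
        pop = {
            "HFWW": synth.CellClassSpec(
                n=3, base_rate_hz=5.0, gains={"V": 0.0}, gamma_shape=1.0,
                half_width_ms=0.3, peak_trough_ratio=0.7, peak_width_factor=2.0,
            )
        }
        cfg = _tiny_config(
            population=pop,
            pair_structure=synth.PairStructureSpec(2, {"V": np.zeros((5, 2))}),
        )
        with pytest.raises(synth.SynthConfigError, match="shape"):
            cfg.validate()

    def test_oscillator_centre_range_enforced(self):
        with pytest.raises(synth.SynthConfigError):
            synth.OscillationSpec(150.0, 5.0, 1.0)

    def test_orthogonal_loadings_are_orthogonal_with_matched_norms(self):
        rng = np.random.default_rng(4)
        L = synth.make_loadings(20, 2, rng)
        Lo = synth.orthogonal_loadings(L, rng)
        assert np.abs(L.T @ Lo).max() < 1e-10
        np.testing.assert_allclose(
            np.linalg.norm(L, axis=0), np.linalg.norm(Lo, axis=0)
        )
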
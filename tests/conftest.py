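"""Shared fixtures: synthetic sessions reused across test modules.

The heavier generated sessions are session-scoped so the suite pays the
generation cost once.
"""

from __future__ import annotations

import numpy as np
import pytest

from neurokinetics import synth
from neurokinetics.io import SpikeUnit
from neurokinetics.preprocess import ConditionWindow, compute_inertial_speed


@pytest.fixture(scope="session")
def coupling_session():
    """20 min single-condition session with three planted oscillators:
    anti-coupled beta (b<0), coupled 50 Hz gamma (b>0) and a high-power
    movement-decoupled 80 Hz rhythm (b=0)."""
    cfg = synth.SynthConfig(
        seed=7,
        duration_min=20.0,
        injection_schedule=[("vehicle", 0.0)],
        movement={"V": synth.MovementSpec(1.5, 0.8)},
        oscillations={
            "V": [
                synth.OscillationSpec(22.0, 10.0, 30.0, -12.0),
                synth.OscillationSpec(50.0, 10.0, 3.0, 12.0),
                synth.OscillationSpec(80.0, 4.0, 45.0, 0.0),
            ]
        },
        population={},
    )
    session, truth = synth.generate_session(cfg)
    speed = compute_inertial_speed(session.imu)
    window = ConditionWindow("V", 0.0, 20.0)
    return session, truth, speed, window


def make_population_config(seed: int = 3) -> synth.SynthConfig:
    """Well-separated 30 IN / 50 LFWW / 100 HFWW population, 20 min."""
    pop = {
        "IN": synth.CellClassSpec(
            n=30, base_rate_hz=12.0, gains={"V": 1.0}, gamma_shape=2.0,
            half_width_ms=0.15, peak_trough_ratio=0.45, peak_width_factor=1.2,
        ),
        "LFWW": synth.CellClassSpec(
            n=50, base_rate_hz=1.5, gains={"V": 0.8}, gamma_shape=0.4,
            half_width_ms=0.35, peak_trough_ratio=0.8, peak_width_factor=2.4,
        ),
        "HFWW": synth.CellClassSpec(
            n=100, base_rate_hz=8.0, gains={"V": 0.8}, gamma_shape=1.0,
            half_width_ms=0.33, peak_trough_ratio=0.75, peak_width_factor=2.2,
        ),
    }
    return synth.SynthConfig(
        seed=seed,
        duration_min=20.0,
        injection_schedule=[("vehicle", 0.0)],
        movement={"V": synth.MovementSpec(1.5, 0.8)},
        oscillations={},
        population=pop,
    )


@pytest.fixture(scope="session")
def population_session():
    session, truth = synth.generate_session(make_population_config())
    speed = compute_inertial_speed(session.imu)
    window = ConditionWindow("V", 0.0, 20.0)
    return session, truth, speed, window


def make_two_state_config(seed: int = 5, n_units: int = 30, reconfigure: bool = True):
    """Two 20 min stationary states sharing latent factors; the second state
    optionally uses loadings orthogonal to the first (planted
    reconfiguration)."""
    rng = np.random.default_rng(1000 + seed)
    L = synth.make_loadings(n_units, 2, rng)
    L2 = synth.orthogonal_loadings(L, rng) if reconfigure else L
    pop = {
        "HFWW": synth.CellClassSpec(
            n=n_units, base_rate_hz=8.0, gains={"V": 0.0, "K": 0.0},
            gamma_shape=1.0, half_width_ms=0.33, peak_trough_ratio=0.75,
            peak_width_factor=2.2,
        )
    }
    return synth.SynthConfig(
        seed=seed,
        duration_min=40.0,
        injection_schedule=[("vehicle", 0.0), ("ketamine", 20.0)],
        movement={"V": synth.MovementSpec(1.0, 0.5), "K": synth.MovementSpec(1.0, 0.5)},
        oscillations={},
        population=pop,
        pair_structure=synth.PairStructureSpec(2, {"V": L, "K": L2}),
    )


@pytest.fixture(scope="session")
def two_state_session():
    session, truth = synth.generate_session(make_two_state_config())
    return session, truth


def make_poisson_units(
    n_units: int, rate_hz: float, duration_s: float, rng: np.random.Generator
) -> list[SpikeUnit]:
    """Independent homogeneous Poisson units (no planted structure)."""
    wf = np.zeros((48, 1))
    wf[16] = -80.0
    wf[28] = 40.0
    units = []
    for i in range(n_units):
        n = rng.poisson(rate_hz * duration_s)
        t = np.sort(rng.uniform(0, duration_s, size=n))
        t = t[np.concatenate([[True], np.diff(t) > 0])]  # strict ordering
        units.append(SpikeUnit(unit_id=f"p{i:02d}", spike_times=t, mean_waveform=wf))
    return units
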
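"""Synthetic recording sessions with planted ground truth.

Every downstream analysis in this package is validated by parameter
recovery, so the generator plants exactly the statistical structure the
analyses assume:

* a rectified Ornstein–Uhlenbeck latent *speed* process with per-condition
  mean and variability, driving a 6-channel random-walk IMU whose recovered
  inertial speed tracks the latent process;
* an LFP built from 1/f^χ background noise plus narrowband oscillators whose
  amplitude is ``a + b·speed(t)`` — b > 0 plants movement coupling, b < 0
  anti-coupling, b = 0 a high-power but movement-decoupled rhythm (the
  dyskinesia-gamma phenotype);
* three spike-train cell classes (IN / LFWW / HFWW) as time-rescaled gamma
  renewal processes with class-specific waveform templates, firing rates,
  burstiness (gamma shape) and per-condition rate↔speed gain;
* optional shared latent factors that inject a pairwise count-correlation
  structure, with per-condition loading matrices so an ensemble
  "reconfiguration" (orthogonal loadings) can be planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (
    IMU_FS,
    LFP_FS,
    InertialTrace,
    InjectionEvent,
    SessionRecording,
    SpeedSeries,
    SpikeUnit,
)

__all__ = [
    "OscillationSpec",
    "MovementSpec",
    "CellClassSpec",
    "PairStructureSpec",
    "SynthConfig",
    "GroundTruth",
    "SynthConfigError",
    "default_config",
    "condition_segments",
    "generate_speed",
    "generate_inertial",
    "generate_lfp",
    "generate_spike_trains",
    "make_loadings",
    "orthogonal_loadings",
    "generate_session",
]


class SynthConfigError(ValueError):
    """Invalid synthetic-session configuration."""


@dataclass(frozen=True)
class OscillationSpec:
    """Narrowband oscillator: centre (Hz), bandwidth (Hz), base amplitude a
    (µV) and movement-coupling gain b, with amplitude(t) = max(0, a + b·s(t))."""

    f0: float
    bw: float
    amp: float
    gain: float = 0.0

    def __post_init__(self) -> None:
        if not 1.0 <= self.f0 <= 120.0:
            raise SynthConfigError(f"oscillator centre {self.f0} Hz outside 1–120 Hz")
        if self.bw <= 0:
            raise SynthConfigError("oscillator bandwidth must be positive")


@dataclass(frozen=True)
class MovementSpec:
    """Latent speed process for one condition (arbitrary inertial units)."""

    mean: float
    sd: float
    timescale_s: float = 2.0

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0:
            raise SynthConfigError("movement mean and SD must be non-negative")


@dataclass(frozen=True)
class CellClassSpec:
    """One cell class: count, waveform template, rate model, burstiness."""

    n: int
    base_rate_hz: float
    gains: dict  # condition label -> rate↔speed gain (Hz per speed unit)
    gamma_shape: float  # renewal shape; <1 bursty (LV>1), 1 Poisson, >1 regular
    half_width_ms: float
    peak_trough_ratio: float
    peak_width_factor: float  # peak half-width relative to trough half-width
    depth_range_um: tuple = (300.0, 2000.0)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise SynthConfigError("unit count must be non-negative")
        if self.gamma_shape <= 0:
            raise SynthConfigError("gamma shape must be positive")


@dataclass(frozen=True)
class PairStructureSpec:
    """Shared latent factors injecting pairwise count correlations.

    ``loadings`` maps condition label → (n_units, n_factors) matrix added to
    each unit's log-rate argument, scaled by unit-variance OU factors.
    """

    n_factors: int
    loadings: dict
    timescale_s: float = 1.0


@dataclass
class SynthConfig:
    seed: int = 0
    duration_min: float = 90.0
    injection_schedule: list = field(default_factory=lambda: [("L-DOPA", 30.0), ("ketamine", 90.0)])
    group: str = "6-OHDA"
    hemisphere: str = "lesioned"
    movement: dict = field(default_factory=dict)  # condition -> MovementSpec
    oscillations: dict = field(default_factory=dict)  # condition -> [OscillationSpec]
    chi: float = 2.0  # 1/f^chi background exponent
    background_rms_uv: float = 50.0
    imu_noise_sd: float = 0.0
    population: dict = field(default_factory=dict)  # class -> CellClassSpec
    pair_structure: PairStructureSpec | None = None
    refractory_ms: float = 2.0
    rate_ceiling_hz: float = 400.0

    def validate(self) -> None:
        for drug, t in self.injection_schedule:
            if not 0 <= t <= self.duration_min:
                raise SynthConfigError(
                    f"injection {drug}@{t} min outside session of {self.duration_min} min"
                )
        if self.pair_structure is not None:
            n_units = sum(c.n for c in self.population.values())
            if n_units == 0:
                raise SynthConfigError("pair structure requested with zero units")
            for cond, L in self.pair_structure.loadings.items():
                L = np.asarray(L)
                if L.shape != (n_units, self.pair_structure.n_factors):
                    raise SynthConfigError(
                        f"loading matrix for {cond!r} has shape {L.shape}, expected "
                        f"({n_units}, {self.pair_structure.n_factors})"
                    )


@dataclass
class GroundTruth:
    """Planted parameters, recorded at generation time and immutable after."""

    condition_segments: list  # (label, start_min, end_min)
    oscillations: dict  # condition -> [OscillationSpec]
    movement: dict  # condition -> MovementSpec
    unit_classes: list  # class label per unit
    unit_gains: list  # dict condition -> gain per unit
    unit_gamma_shapes: list
    pair_loadings: dict  # condition -> (n_units, n_factors) array
    latent_speed: SpeedSeries | None = None


# ---------------------------------------------------------------------------
# condition timeline


def condition_segments(
    schedule: list, duration_min: float
) -> list[tuple[str, float, float]]:
    """Piecewise condition labels over the session timeline.

    Pre-injection time is baseline (BL); each injection opens a new segment.
    L-DOPA followed by vehicle stays in the LD state (vehicle is the
    control); ketamine after L-DOPA opens the LD→K state.
    """
    ev = sorted(schedule, key=lambda e: e[1])
    segs: list[tuple[str, float, float]] = []
    t_prev, label = 0.0, "BL"
    prior_ld = False
    for drug, t in ev:
        if t > t_prev:
            segs.append((label, t_prev, t))
        if drug == "L-DOPA":
            label, prior_ld = "LD", True
        elif drug == "ketamine":
            label = "LD->K" if prior_ld else "K"
        elif drug == "vehicle":
            label = label if prior_ld else "V"
        else:
            raise SynthConfigError(f"unknown drug {drug!r}")
        t_prev = t
    if duration_min > t_prev:
        segs.append((label, t_prev, duration_min))
    return segs


# ---------------------------------------------------------------------------
# movement


def generate_speed(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[SpeedSeries, list[tuple[str, float, float]]]:
    """Rectified OU latent speed with per-condition mean/SD at 200 Hz."""
    segs = condition_segments(config.injection_schedule, config.duration_min)
    n = int(round(config.duration_min * 60.0 * IMU_FS))
    dt = 1.0 / IMU_FS
    mu = np.zeros(n)
    sd = np.zeros(n)
    tau = np.full(n, 2.0)
    for label, t0, t1 in segs:
        spec = config.movement.get(label, MovementSpec(0.0, 0.0))
        i0, i1 = int(round(t0 * 60 * IMU_FS)), int(round(t1 * 60 * IMU_FS))
        mu[i0:i1] = spec.mean
        sd[i0:i1] = spec.sd
        tau[i0:i1] = spec.timescale_s
    x = np.empty(n)
    x[0] = mu[0]
    eps = rng.standard_normal(n - 1)
    alpha = dt / tau[1:]
    diff = sd[1:] * np.sqrt(2.0 * alpha)
    for i in range(1, n):
        x[i] = x[i - 1] + alpha[i - 1] * (mu[i] - x[i - 1]) + diff[i - 1] * eps[i - 1]
    return SpeedSeries(np.maximum(x, 0.0), fs=IMU_FS), segs


def generate_inertial(
    speed: SpeedSeries, rng: np.random.Generator, noise_sd: float = 0.0
) -> InertialTrace:
    """6-channel IMU whose per-sample increments scale with the latent speed.

    Each channel is a random walk with Gaussian increments of scale
    ``speed·√(π/2)``, so the folded increment has expectation equal to the
    latent speed and ``compute_inertial_speed`` recovers it up to noise.
    """
    if noise_sd < 0:
        raise SynthConfigError("IMU noise SD must be non-negative")
    s = speed.values
    z = rng.standard_normal((s.size, 6))
    steps = s[:, None] * np.sqrt(np.pi / 2.0) * z
    if noise_sd > 0:
        steps = steps + noise_sd * rng.standard_normal(steps.shape)
    data = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
    return InertialTrace(data, fs=speed.fs)


# ---------------------------------------------------------------------------
# LFP


def _one_over_f_noise(n: int, chi: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise spectrally shaped to a 1/f^chi power spectrum, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-chi / 2.0)
    x = np.fft.irfft(spec * scale, n=n)
    return x / x.std()


def _narrowband_carrier(
    n: int, fs: float, f0: float, bw: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS bandpass-filtered Gaussian noise around f0."""
    from scipy import signal as sps

    lo = max(f0 - bw / 2.0, 0.5)
    hi = min(f0 + bw / 2.0, fs / 2.0 - 1.0)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def generate_lfp(
    config: SynthConfig,
    speed: SpeedSeries,
    segs: list,
    rng: np.random.Generator,
) -> np.ndarray:
    """1/f^χ background plus condition-gated movement-modulated oscillators."""
    n = int(round(config.duration_min * 60.0 * LFP_FS))
    lfp = config.background_rms_uv * _one_over_f_noise(n, config.chi, rng)
    if not any(config.oscillations.values()):
        return lfp
    # latent speed on the LFP timebase
    t_lfp = np.arange(n) / LFP_FS
    t_imu = np.arange(speed.values.size) / speed.fs
    s500 = np.interp(t_lfp, t_imu, speed.values)
    for label, t0, t1 in segs:
        oscs = config.oscillations.get(label, [])
        if not oscs:
            continue
        i0, i1 = int(round(t0 * 60 * LFP_FS)), int(round(t1 * 60 * LFP_FS))
        for osc in oscs:
            carrier = _narrowband_carrier(i1 - i0, LFP_FS, osc.f0, osc.bw, rng)
            env = np.maximum(osc.amp + osc.gain * s500[i0:i1], 0.0)
            lfp[i0:i1] += env * carrier
    return lfp


# ---------------------------------------------------------------------------
# spike trains


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sample_renewal_train(
    lam: np.ndarray,
    fs: float,
    shape: float,
    refractory_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Time-rescaled gamma renewal process with intensity ``lam`` (Hz).

    Unit-rate gamma intervals (shape k, scale 1/k) are generated in rescaled
    time and mapped back through the inverse cumulative intensity, which
    imposes λ(t) while leaving the ISI regularity (hence LV) set by k.  A
    dead time is enforced afterwards by dropping violating spikes.
    """
    cum = np.concatenate([[0.0], np.cumsum(lam) / fs])  # rescaled time at sample edges
    total = cum[-1]
    if total <= 0:
        return np.array([])
    n_exp = int(total) + 1
    intervals = rng.gamma(shape, 1.0 / shape, size=max(2 * n_exp + 20, 64))
    arrivals = np.cumsum(intervals)
    while arrivals[-1] < total:
        more = rng.gamma(shape, 1.0 / shape, size=arrivals.size)
        arrivals = np.concatenate([arrivals, arrivals[-1] + np.cumsum(more)])
    arrivals = arrivals[arrivals < total]
    t_edges = np.arange(cum.size) / fs
    spikes = np.interp(arrivals, cum, t_edges)
    if refractory_s > 0 and spikes.size > 1:
        keep = [0]
        last = spikes[0]
        for i in range(1, spikes.size):
            if spikes[i] - last >= refractory_s:
                keep.append(i)
                last = spikes[i]
        spikes = spikes[keep]
    return spikes


def _waveform_template(
    spec: CellClassSpec, rng: np.random.Generator, fs: float = 30000.0, n: int = 48
) -> np.ndarray:
    """Biphasic template (trough then peak) with per-unit feature jitter,
    replicated over 4 tetrode channels with decaying amplitude."""
    jitter = lambda v, frac=0.05: v * (1.0 + frac * rng.standard_normal())  # noqa: E731
    hw_ms = max(jitter(spec.half_width_ms), 0.05)
    ptr = np.clip(jitter(spec.peak_trough_ratio), 0.05, 3.0)
    pwf = max(jitter(spec.peak_width_factor), 0.3)
    sigma_t = hw_ms / 1000.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_p = pwf * sigma_t
    t = np.arange(n) / fs
    t0 = n / fs * 0.35
    t1 = t0 + 2.5 * sigma_t + 1.5 * sigma_p
    amp = 80.0 * (1.0 + 0.1 * rng.standard_normal())
    x = -amp * np.exp(-((t - t0) ** 2) / (2 * sigma_t**2))
    x = x + amp * ptr * np.exp(-((t - t1) ** 2) / (2 * sigma_p**2))
    scales = np.array([1.0, 0.35, 0.2, 0.1])
    rng.shuffle(scales)
    scales[np.argmax(scales)] = 1.0  # exactly one dominant channel
    return x[:, None] * scales[None, :]


def _latent_factors(
    n_samples: int, n_factors: int, timescale_s: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance OU factor processes, (n_samples, n_factors)."""
    dt = 1.0 / fs
    alpha = dt / timescale_s
    f = np.zeros((n_samples, n_factors))
    eps = rng.standard_normal((n_samples - 1, n_factors))
    f[0] = rng.standard_normal(n_factors)
    c = np.sqrt(2.0 * alpha)
    for i in range(1, n_samples):
        f[i] = f[i - 1] * (1 - alpha) + c * eps[i - 1]
    return f


def generate_spike_trains(
    config: SynthConfig,
    speed: SpeedSeries,
    segs: list,
    rng: np.random.Generator,
) -> tuple[list[SpikeUnit], list[str], list[dict], list[float]]:
    """Spike trains for the configured population.

    Rate model per unit: λ(t) = softplus(base + gain_cond(t)·s(t) + factor
    drive), sampled by time-rescaled gamma renewal with a hard dead time.
    Returns (units, class labels, per-unit gain dicts, gamma shapes).
    """
    s = speed.values
    n = s.size
    cond_idx = np.empty(n, dtype=object)
    for label, t0, t1 in segs:
        i0, i1 = int(round(t0 * 60 * speed.fs)), int(round(t1 * 60 * speed.fs))
        cond_idx[i0:i1] = label

    n_units = sum(spec.n for spec in config.population.values())
    factors = None
    loadings_by_cond: dict = {}
    if config.pair_structure is not None and n_units:
        factors = _latent_factors(
            n, config.pair_structure.n_factors, config.pair_structure.timescale_s,
            speed.fs, rng,
        )
        loadings_by_cond = {
            c: np.asarray(L, dtype=np.float64)
            for c, L in config.pair_structure.loadings.items()
        }

    units: list[SpikeUnit] = []
    classes: list[str] = []
    gains_out: list[dict] = []
    shapes_out: list[float] = []
    u = 0
    for cls, spec in config.population.items():
        # base chosen so softplus(base) = base rate at zero speed
        base = float(np.log(np.expm1(spec.base_rate_hz))) if spec.base_rate_hz > 0 else -20.0
        for _ in range(spec.n):
            gain_t = np.zeros(n)
            for label, t0, t1 in segs:
                g = spec.gains.get(label, 0.0)
                i0 = int(round(t0 * 60 * speed.fs))
                i1 = int(round(t1 * 60 * speed.fs))
                gain_t[i0:i1] = g
            arg = base + gain_t * s
            if factors is not None:
                drive = np.zeros(n)
                for label, t0, t1 in segs:
                    L = loadings_by_cond.get(label)
                    if L is None:
                        continue
                    i0 = int(round(t0 * 60 * speed.fs))
                    i1 = int(round(t1 * 60 * speed.fs))
                    drive[i0:i1] = factors[i0:i1] @ L[u]
                arg = arg + drive
            lam = _softplus(arg)
            if lam.max() > config.rate_ceiling_hz:
                raise SynthConfigError(
                    f"intensity {lam.max():.1f} Hz exceeds ceiling "
                    f"{config.rate_ceiling_hz} Hz for class {cls}"
                )
            spikes = _sample_renewal_train(
                lam, speed.fs, spec.gamma_shape, config.refractory_ms / 1000.0, rng
            )
            wf = _waveform_template(spec, rng)
            depth = rng.uniform(*spec.depth_range_um)
            units.append(
                SpikeUnit(
                    unit_id=f"u{u:03d}",
                    spike_times=spikes,
                    mean_waveform=wf,
                    depth_um=float(depth),
                )
            )
            classes.append(cls)
            gains_out.append(dict(spec.gains))
            shapes_out.append(spec.gamma_shape)
            u += 1
    return units, classes, gains_out, shapes_out


# ---------------------------------------------------------------------------
# pair-structure helpers


def make_loadings(
    n_units: int, n_factors: int, rng: np.random.Generator, scale: float = 2.5
) -> np.ndarray:
    """Random dense loading matrix; per-unit factor drive has SD ≈ ``scale``."""
    return scale * rng.standard_normal((n_units, n_factors)) / np.sqrt(n_factors)


def orthogonal_loadings(L: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Loadings with the same column norms as ``L`` but orthogonal columns
    (in unit space) to it — a planted ensemble reconfiguration that changes
    the pair-correlation pattern without changing its magnitude."""
    n, k = L.shape
    norms = np.linalg.norm(L, axis=0)
    raw = rng.standard_normal((n, k))
    basis, _ = np.linalg.qr(L)
    raw -= basis @ (basis.T @ raw)
    raw /= np.linalg.norm(raw, axis=0, keepdims=True)
    return raw * norms


# ---------------------------------------------------------------------------
# defaults and the top-level generator


def default_population(speed_gain_scale: float = 1.0) -> dict:
    """Default three-class population mirroring the tetrode phenomenology:
    narrow high-rate IN, bursty low-rate LFWW (LV > 1), near-Poisson HFWW.

    Rate↔speed gains are positive in BL/V/K, zero under LD (the planted
    movement decoupling) and partially restored under LD→K.
    """
    g = speed_gain_scale
    common = {"BL": 0.8 * g, "V": 0.8 * g, "K": 0.8 * g, "LD": 0.0, "LD->K": 0.4 * g}
    return {
        "IN": CellClassSpec(
            n=6, base_rate_hz=12.0, gains={k: 1.5 * v for k, v in common.items()},
            gamma_shape=2.0, half_width_ms=0.15, peak_trough_ratio=0.45,
            peak_width_factor=1.2, depth_range_um=(300.0, 2000.0),
        ),
        "LFWW": CellClassSpec(
            n=10, base_rate_hz=1.5, gains=dict(common),
            gamma_shape=0.4, half_width_ms=0.35, peak_trough_ratio=0.8,
            peak_width_factor=2.4, depth_range_um=(300.0, 2000.0),
        ),
        "HFWW": CellClassSpec(
            n=20, base_rate_hz=8.0, gains=dict(common),
            gamma_shape=1.0, half_width_ms=0.33, peak_trough_ratio=0.75,
            peak_width_factor=2.2, depth_range_um=(300.0, 2000.0),
        ),
    }


def default_movement() -> dict:
    """Condition mean/SD of the latent speed (arbitrary units): movement is
    low at baseline, raised by ketamine and highest during dyskinesia."""
    return {
        "BL": MovementSpec(0.8, 0.4),
        "V": MovementSpec(1.0, 0.5),
        "K": MovementSpec(1.6, 0.8),
        "LD": MovementSpec(2.6, 1.2),
        "LD->K": MovementSpec(2.6, 1.4),
    }


def default_oscillations(hemisphere: str = "lesioned") -> dict:
    """Condition-dependent oscillators for the dopamine-depleted hemisphere:
    movement-anti-coupled beta at BL/V, movement-coupled broadband gamma at
    V/K, ~50 Hz ketamine gamma, and high-power movement-decoupled ~80 Hz
    gamma under L-DOPA (the dyskinesia signature).  Control hemispheres get
    only the broadband movement gamma and the ketamine gamma."""
    broadband = OscillationSpec(f0=70.0, bw=80.0, amp=2.0, gain=8.0)
    k_gamma = OscillationSpec(f0=50.0, bw=10.0, amp=3.0, gain=12.0)
    if hemisphere == "lesioned":
        beta = OscillationSpec(f0=22.0, bw=10.0, amp=30.0, gain=-12.0)
        ftg = OscillationSpec(f0=80.0, bw=4.0, amp=45.0, gain=0.0)
        flat_broadband = OscillationSpec(f0=70.0, bw=80.0, amp=2.0, gain=0.0)
        return {
            "BL": [beta, broadband],
            "V": [beta, broadband],
            "K": [k_gamma, broadband],
            "LD": [ftg, flat_broadband],  # decoupled gamma: power without coupling
            "LD->K": [k_gamma, OscillationSpec(80.0, 4.0, 8.0, 0.0), broadband],
        }
    return {
        "BL": [broadband],
        "V": [broadband],
        "K": [k_gamma, broadband],
        "LD": [broadband],
        "LD->K": [k_gamma, broadband],
    }


def default_config(
    seed: int = 0,
    session_type: str = "LD->K",
    group: str = "6-OHDA",
    hemisphere: str = "lesioned",
    duration_min: float | None = None,
    schedule: list | None = None,
    n_factors: int = 0,
    reconfigure_condition: str | None = None,
) -> SynthConfig:
    """A ready-to-run session configuration for one of the three session
    types (``"V->K"``, ``"LD->V"``, ``"LD->K"``)."""
    schedules = {
        "V->K": [("vehicle", 30.0), ("ketamine", 60.0)],
        "LD->V": [("L-DOPA", 30.0), ("vehicle", 90.0)],
        "LD->K": [("L-DOPA", 30.0), ("ketamine", 90.0)],
    }
    durations = {"V->K": 90.0, "LD->V": 120.0, "LD->K": 120.0}
    if session_type not in schedules:
        raise SynthConfigError(f"unknown session type {session_type!r}")
    cfg = SynthConfig(
        seed=seed,
        duration_min=duration_min or durations[session_type],
        injection_schedule=schedule or schedules[session_type],
        group=group,
        hemisphere=hemisphere,
        movement=default_movement(),
        oscillations=default_oscillations(hemisphere if group == "6-OHDA" else "intact"),
        population=default_population(),
    )
    if n_factors:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 917]))
        n_units = sum(c.n for c in cfg.population.values())
        base_L = make_loadings(n_units, n_factors, rng)
        segs = condition_segments(cfg.injection_schedule, cfg.duration_min)
        loadings = {label: base_L for label, _, _ in segs}
        if reconfigure_condition is not None:
            loadings[reconfigure_condition] = orthogonal_loadings(base_L, rng)
        cfg.pair_structure = PairStructureSpec(n_factors=n_factors, loadings=loadings)
    return cfg


def generate_session(config: SynthConfig) -> tuple[SessionRecording, GroundTruth]:
    """Generate a full synthetic session plus its planted ground truth.

    Deterministic given ``config.seed``: independent child RNG streams per
    component (movement, IMU, LFP, spikes) keep each component reproducible
    when others change.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_move, rng_imu, rng_lfp, rng_spk = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    speed, segs = generate_speed(config, rng_move)
    imu = generate_inertial(speed, rng_imu, config.imu_noise_sd)
    lfp = generate_lfp(config, speed, segs, rng_lfp)
    units, classes, gains, shapes = generate_spike_trains(config, speed, segs, rng_spk)

    session = SessionRecording(
        session_id=f"synth-{config.seed}",
        group=config.group,
        hemisphere=config.hemisphere,
        lfp=lfp,
        lfp_fs=LFP_FS,
        imu=imu,
        units=units,
        events=[InjectionEvent(d, t) for d, t in config.injection_schedule],
    )
    truth = GroundTruth(
        condition_segments=segs,
        oscillations={k: list(v) for k, v in config.oscillations.items()},
        movement=dict(config.movement),
        unit_classes=classes,
        unit_gains=gains,
        unit_gamma_shapes=shapes,
        pair_loadings=(
            {c: np.array(L, copy=True) for c, L in config.pair_structure.loadings.items()}
            if config.pair_structure
            else {}
        ),
        latent_speed=speed,
    )
    return session, truth
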
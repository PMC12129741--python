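"""End-to-end pipeline over synthetic cohorts.

Generates a cohort of sessions, runs every analysis stage per condition
window (movement, spectral coupling, band regressions, unit typing and
timescale coupling, ensemble state similarity and pair deltas), and emits
summary tables, group comparisons and a ground-truth recovery report.

Two session-timeline schemes are provided: the full scheme with the
experiment's injection times and 20 min windows, and a compact scheme (same
structure, shorter windows) intended for smoke runs and calibration sweeps.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import synth, units as units_mod
from .coupling import BandSpeedRegression, PowerSpeedCoupling, population_timescale_coupling
from .ensembles import pair_correlation_change, pairwise_correlations, state_similarity
from .preprocess import compute_inertial_speed, resolve_condition_windows
from .spectral import BANDS, compute_spectrogram
from .stats import holm_adjust

log = logging.getLogger(__name__)

#: compact timeline: injections at 6 and 13 min, 5 min analysis windows
COMPACT = {
    "duration_min": 20.0,
    "schedules": {
        "V->K": [("vehicle", 6.0), ("ketamine", 13.0)],
        "LD->V": [("L-DOPA", 6.0), ("vehicle", 13.0)],
        "LD->K": [("L-DOPA", 6.0), ("ketamine", 13.0)],
    },
    "offsets": {
        "BL": (-5.0, -1.0),
        "V": (1.0, 6.0),
        "K": (1.0, 6.0),
        "LD": (8.0, 13.0),
        "LD->K": (1.0, 6.0),
        "LD-early": (1.0, 6.0),
    },
}


@dataclass
class CohortConfig:
    """Synthetic cohort: animals × session types, plus analysis parameters."""

    n_animals: int = 2  # per group
    groups: tuple = ("6-OHDA",)
    session_types: tuple = ("V->K", "LD->V", "LD->K")
    seed: int = 0
    compact: bool = True
    n_factors: int = 2
    reconfigure_on_ketamine: bool = True
    null_model: bool = False  # no planted effects anywhere
    alpha: float = 0.05
    pair_bin_s: float = 1.0
    outdir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _session_config(cohort: CohortConfig, group: str, animal: int, stype: str, seed: int):
    reconf = None
    if cohort.reconfigure_on_ketamine and not cohort.null_model:
        reconf = {"V->K": "K", "LD->V": None, "LD->K": "LD->K"}[stype]
    hemisphere = "lesioned"
    kwargs = {}
    if cohort.compact:
        kwargs = dict(
            duration_min=COMPACT["duration_min"],
            schedule=COMPACT["schedules"][stype],
        )
    cfg = synth.default_config(
        seed=seed,
        session_type=stype,
        group=group,
        hemisphere=hemisphere,
        n_factors=cohort.n_factors,
        reconfigure_condition=reconf,
        **kwargs,
    )
    if cohort.null_model:
        flat = synth.MovementSpec(1.0, 0.5)
        cfg.movement = {k: flat for k in cfg.movement}
        cfg.oscillations = {}
        cfg.population = {
            cls: synth.CellClassSpec(
                n=spec.n, base_rate_hz=spec.base_rate_hz,
                gains={k: 0.0 for k in spec.gains},
                gamma_shape=spec.gamma_shape, half_width_ms=spec.half_width_ms,
                peak_trough_ratio=spec.peak_trough_ratio,
                peak_width_factor=spec.peak_width_factor,
                depth_range_um=spec.depth_range_um,
            )
            for cls, spec in cfg.population.items()
        }
        if cfg.pair_structure is not None:
            zero = {c: np.zeros_like(L) for c, L in cfg.pair_structure.loadings.items()}
            cfg.pair_structure = synth.PairStructureSpec(
                n_factors=cohort.n_factors, loadings=zero
            )
    return cfg


def analyse_session(session, truth, cohort: CohortConfig, animal_id: str, stype: str):
    """Run all analysis stages on one session; returns per-stage tables."""
    offsets = COMPACT["offsets"] if cohort.compact else None
    windows = resolve_condition_windows(
        session.events, session.duration_s / 60.0, offsets=offsets
    )
    win_by_label = {w.label: w for w in windows}
    speed = compute_inertial_speed(session.imu)

    movement_rows, coupling_rows, band_rows = [], [], []
    for w in windows:
        sp = speed.slice(w.start_s, w.end_s)
        movement_rows.append(
            dict(animal=animal_id, session_type=stype, condition=w.label,
                 mean_speed=float(sp.mean()), sd_speed=float(sp.std())),
        )
        spec = compute_spectrogram(session.lfp_slice(w.start_s, w.end_s))
        cres = PowerSpeedCoupling(spec, speed, w).fit()
        row = dict(animal=animal_id, session_type=stype, condition=w.label,
                   n_frames=cres.nobs)
        for name, band in BANDS.items():
            row[f"r_{name}"] = cres.band_mean(band)
            m = (cres.freqs >= band[0]) & (cres.freqs <= band[1])
            row[f"abs_r_{name}"] = float(np.nanmean(np.abs(cres.rvalues[m])))
        coupling_rows.append(row)
        for name in ("beta", "gamma"):
            bres = BandSpeedRegression(spec, speed, BANDS[name], w).fit()
            band_rows.append(
                dict(animal=animal_id, session_type=stype, condition=w.label,
                     band=name, adj_r2=bres.rsquared_adj, n_frames=bres.nobs),
            )

    # unit characterisation (once per session)
    feats, lags, rates, keep = [], [], [], []
    for i, u in enumerate(session.units):
        if u.n_spikes < 10:
            continue
        try:
            f = units_mod.extract_waveform_features(u.mean_waveform, u.waveform_fs)
        except units_mod.WaveformError:
            continue
        acg = units_mod.compute_autocorrelogram(u.spike_times)
        ok, _ = units_mod.unit_inclusion(u.spike_times, windows, acg)
        if not ok:
            continue
        feats.append(f)
        lags.append(acg.peak_lag_ms)
        rates.append(u.n_spikes / session.duration_s)
        keep.append(i)
    unit_rows = []
    if len(feats) >= 4:
        labels = units_mod.classify_cell_types(feats, np.array(lags), np.array(rates))
        for lab, i in zip(labels, keep):
            u = session.units[i]
            u.cell_type = lab.label
            u.layer = units_mod.assign_layer(u.depth_um)
            u.included = True
            if u.n_spikes >= 3:
                u.lv = units_mod.local_variance(u.spike_times)
            unit_rows.append(
                dict(animal=animal_id, session_type=stype, unit_id=u.unit_id,
                     cell_type=lab.label, true_class=truth.unit_classes[i],
                     layer=u.layer, lv=u.lv, rate_hz=lab.firing_rate_hz),
            )

    included_units = [session.units[i] for i in keep]

    ts_rows = []
    for w in windows:
        df = population_timescale_coupling(included_units, speed, w, condition=w.label)
        per_unit = (
            df.loc[~df["silent"]]
            .groupby("unit_id")["r2"].mean()
            .rename("mean_r2").reset_index()
        )
        per_unit["animal"] = animal_id
        per_unit["session_type"] = stype
        per_unit["condition"] = w.label
        ts_rows.append(per_unit)
    ts = pd.concat(ts_rows, ignore_index=True) if ts_rows else pd.DataFrame()

    # ensembles: baseline vs each post state
    ens_rows, delta_rows = [], []
    if len(included_units) >= 2 and "BL" in win_by_label:
        pre = pairwise_correlations(
            included_units, win_by_label["BL"], cohort.pair_bin_s,
            session_id=session.session_id,
        )
        for label, w in win_by_label.items():
            if label == "BL":
                continue
            post = pairwise_correlations(
                included_units, w, cohort.pair_bin_s, session_id=session.session_id
            )
            sim = state_similarity(pre, post)
            ens_rows.append(
                dict(animal=animal_id, session_type=stype, state_a="BL",
                     state_b=label, similarity=sim.similarity, n_pairs=sim.n_pairs),
            )
            try:
                delta = pair_correlation_change(pre, post, cohort.alpha)
                delta_rows.append(
                    dict(animal=animal_id, session_type=stype, condition=label,
                         mean_delta=delta.mean_delta,
                         mean_abs_delta=delta.mean_abs_delta,
                         wilcoxon_p=delta.wilcoxon_p, n_pairs=delta.n_pairs),
                )
            except ValueError:
                log.info("no significant pairs for %s/%s", stype, label)

    return {
        "movement": pd.DataFrame(movement_rows),
        "coupling": pd.DataFrame(coupling_rows),
        "band_regression": pd.DataFrame(band_rows),
        "units": pd.DataFrame(unit_rows),
        "timescale": ts,
        "similarity": pd.DataFrame(ens_rows),
        "pair_deltas": pd.DataFrame(delta_rows),
    }


def _group_tests(tables: dict, alpha: float) -> pd.DataFrame:
    """Condition-effect tests on the pooled summary tables (harness layer)."""
    rows = []

    def add(name, groups):
        groups = [np.asarray(g, dtype=float) for g in groups if len(g) >= 2]
        if len(groups) < 2:
            return
        h, p = sps.kruskal(*groups)
        rows.append(dict(measure=name, test="kruskal", stat=float(h), p=float(p)))

    mv = tables["movement"]
    if not mv.empty:
        add("mean_speed", [g["mean_speed"].to_numpy() for _, g in mv.groupby("condition")])
    ts = tables["timescale"]
    if not ts.empty:
        add("unit_mean_r2", [g["mean_r2"].to_numpy() for _, g in ts.groupby("condition")])
    br = tables["band_regression"]
    if not br.empty:
        for band, sub in br.groupby("band"):
            add(f"adj_r2_{band}", [g["adj_r2"].to_numpy() for _, g in sub.groupby("condition")])
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_holm"] = holm_adjust(out["p"].to_numpy())
        out["significant"] = out["p_holm"] <= alpha
    return out


def run_full_pipeline(cohort: CohortConfig) -> dict:
    """Generate and analyse the whole cohort; returns a dict of tables.

    Deterministic under ``cohort.seed``; per-session seeds are spawned from
    it so sessions are independently reproducible.  When ``outdir`` is set,
    every table is written as CSV beside a manifest with the config hash.
    """
    tables: dict[str, list] = {}
    recovery_rows = []
    session_idx = 0
    for group in cohort.groups:
        for a in range(cohort.n_animals):
            animal_id = f"{group}-a{a}"
            for stype in cohort.session_types:
                group_key = int.from_bytes(
                    hashlib.sha256(group.encode()).digest()[:2], "little"
                )
                seed = int(
                    np.random.SeedSequence(
                        [cohort.seed, group_key, a, session_idx]
                    ).generate_state(1)[0] % (2**31)
                )
                cfg = _session_config(cohort, group, a, stype, seed)
                session, truth = synth.generate_session(cfg)
                out = analyse_session(session, truth, cohort, animal_id, stype)
                for k, v in out.items():
                    tables.setdefault(k, []).append(v)
                if not out["units"].empty:
                    agree = (out["units"]["cell_type"] == out["units"]["true_class"]).mean()
                    recovery_rows.append(
                        dict(animal=animal_id, session_type=stype,
                             measure="cell_type_recovery", value=float(agree)),
                    )
                session_idx += 1

    merged = {
        k: pd.concat(v, ignore_index=True) if v else pd.DataFrame()
        for k, v in tables.items()
    }
    merged["recovery"] = pd.DataFrame(recovery_rows)
    merged["group_tests"] = _group_tests(merged, cohort.alpha)

    if cohort.outdir:
        outdir = Path(cohort.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {"config_hash": cohort.config_hash(), "tables": {}}
        for name, df in merged.items():
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=False)
            manifest["tables"][name] = path.name
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return merged
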
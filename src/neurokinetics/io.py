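"""Session containers and the on-disk session-bundle format.

A recording session couples one motor-cortex LFP channel per hemisphere with
a 6-channel head-mounted inertial trace, a population of sorted single units
(spike times + mean waveform + recording depth) and the injection events that
define the drug conditions.

The bundle layout is a plain directory::

    session/
      session.json     metadata, sample rates, injection events
      lfp.f32          little-endian float32 LFP vector (or lfp.csv)
      imu.f32          6 interleaved float32 channels (or imu.csv)
      spikes.tsv       unit_id <TAB> spike_time_s
      waveforms.csv    unit_id,channel,sample_index,uv
      depths.csv       unit_id,depth_um
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DRUG_VOCABULARY = ("vehicle", "ketamine", "L-DOPA")

IMU_FS = 200.0
LFP_FS = 500.0


class BundleError(ValueError):
    """Malformed or incomplete session bundle."""


@dataclass
class InjectionEvent:
    drug: str
    time_min: float

    def __post_init__(self) -> None:
        if self.drug not in DRUG_VOCABULARY:
            raise BundleError(
                f"unknown drug label {self.drug!r}; expected one of {DRUG_VOCABULARY}"
            )


@dataclass
class InertialTrace:
    """6-channel inertial trace (accel x/y/z + gyro x/y/z, arbitrary units)."""

    data: np.ndarray  # (n_samples, 6)
    fs: float = IMU_FS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[1] != 6:
            raise BundleError(
                f"inertial trace must have 6 channels, got shape {self.data.shape}"
            )
        if self.fs <= 0:
            raise BundleError("inertial sample rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class SpeedSeries:
    """Scalar inertial speed: mean |first difference| across the 6 channels."""

    values: np.ndarray
    fs: float = IMU_FS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("inertial speed is non-negative by construction")

    def slice(self, start_s: float, end_s: float) -> np.ndarray:
        i0 = int(round(start_s * self.fs))
        i1 = int(round(end_s * self.fs))
        return self.values[i0:i1]


@dataclass
class SpikeUnit:
    """One sorted unit: spike times, mean waveform and derived labels."""

    unit_id: str
    spike_times: np.ndarray  # seconds, strictly increasing
    mean_waveform: np.ndarray  # (n_samples, n_channels), µV
    depth_um: float = 0.0
    waveform_fs: float = 30000.0
    cell_type: str | None = None
    layer: str | None = None
    lv: float | None = None
    included: bool | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=np.float64)
        self.mean_waveform = np.atleast_2d(np.asarray(self.mean_waveform, dtype=np.float64))
        if self.mean_waveform.size == 0:
            raise BundleError(f"unit {self.unit_id}: empty waveform")
        if self.spike_times.size > 1 and np.any(np.diff(self.spike_times) <= 0):
            raise BundleError(f"unit {self.unit_id}: spike times not strictly increasing")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    def rate_in(self, start_s: float, end_s: float) -> float:
        n = np.count_nonzero((self.spike_times >= start_s) & (self.spike_times < end_s))
        return n / (end_s - start_s)


@dataclass
class SessionRecording:
    session_id: str
    group: str  # {"sham", "6-OHDA"}
    hemisphere: str  # {"lesioned", "intact"}
    lfp: np.ndarray
    lfp_fs: float
    imu: InertialTrace
    units: list[SpikeUnit]
    events: list[InjectionEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lfp = np.asarray(self.lfp, dtype=np.float64)
        if self.lfp_fs <= 0:
            raise BundleError("LFP sample rate must be positive")
        dur = self.duration_s
        for ev in self.events:
            if not 0 <= ev.time_min * 60 <= dur:
                raise BundleError(
                    f"event {ev.drug}@{ev.time_min}min outside session of {dur:.0f}s"
                )
        for u in self.units:
            if u.n_spikes and (u.spike_times[0] < 0 or u.spike_times[-1] > dur):
                raise BundleError(f"unit {u.unit_id}: spike times outside session")

    @property
    def duration_s(self) -> float:
        return self.lfp.size / self.lfp_fs

    def lfp_slice(self, start_s: float, end_s: float) -> np.ndarray:
        i0 = int(round(start_s * self.lfp_fs))
        i1 = int(round(end_s * self.lfp_fs))
        return self.lfp[i0:i1]


# ---------------------------------------------------------------------------
# bundle I/O

_REQUIRED = ("session.json", "spikes.tsv", "waveforms.csv", "depths.csv")


def write_session(session: SessionRecording, path: str | Path, fmt: str = "f32") -> Path:
    """Write a session bundle; ``fmt`` selects binary f32 or csv traces."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "session_id": session.session_id,
        "group": session.group,
        "hemisphere": session.hemisphere,
        "lfp_fs": session.lfp_fs,
        "imu_fs": session.imu.fs,
        "trace_format": fmt,
        "events": [{"drug": e.drug, "time_min": e.time_min} for e in session.events],
        "waveform_fs": session.units[0].waveform_fs if session.units else 30000.0,
    }
    (path / "session.json").write_text(json.dumps(meta, indent=1))
    if fmt == "f32":
        session.lfp.astype("<f4").tofile(path / "lfp.f32")
        session.imu.data.astype("<f4").tofile(path / "imu.f32")
    elif fmt == "csv":
        np.savetxt(path / "lfp.csv", session.lfp, fmt="%.8g", header="uv", comments="")
        np.savetxt(
            path / "imu.csv", session.imu.data, fmt="%.8g", delimiter=",",
            header="ax,ay,az,gx,gy,gz", comments="",
        )
    else:
        raise ValueError(f"unknown trace format {fmt!r}")

    rows = [
        (u.unit_id, t) for u in session.units for t in u.spike_times
    ]
    pd.DataFrame(rows, columns=["unit_id", "spike_time_s"]).to_csv(
        path / "spikes.tsv", sep="\t", index=False
    )
    wf_rows = []
    for u in session.units:
        ns, nc = u.mean_waveform.shape
        for c in range(nc):
            for s in range(ns):
                wf_rows.append((u.unit_id, c, s, u.mean_waveform[s, c]))
    pd.DataFrame(wf_rows, columns=["unit_id", "channel", "sample_index", "uv"]).to_csv(
        path / "waveforms.csv", index=False
    )
    pd.DataFrame(
        [(u.unit_id, u.depth_um) for u in session.units],
        columns=["unit_id", "depth_um"],
    ).to_csv(path / "depths.csv", index=False)
    return path


def read_session(path: str | Path) -> SessionRecording:
    path = Path(path)
    for name in _REQUIRED:
        if not (path / name).exists():
            raise BundleError(f"session bundle missing part: {name}")
    meta = json.loads((path / "session.json").read_text())
    fmt = meta.get("trace_format", "f32")
    if fmt == "f32":
        for name in ("lfp.f32", "imu.f32"):
            if not (path / name).exists():
                raise BundleError(f"session bundle missing part: {name.split('.')[0]}")
        lfp = np.fromfile(path / "lfp.f32", dtype="<f4").astype(np.float64)
        imu_flat = np.fromfile(path / "imu.f32", dtype="<f4").astype(np.float64)
        imu = InertialTrace(imu_flat.reshape(-1, 6), fs=meta["imu_fs"])
    else:
        for name in ("lfp.csv", "imu.csv"):
            if not (path / name).exists():
                raise BundleError(f"session bundle missing part: {name.split('.')[0]}")
        lfp = np.loadtxt(path / "lfp.csv", skiprows=1)
        imu = InertialTrace(
            np.loadtxt(path / "imu.csv", delimiter=",", skiprows=1), fs=meta["imu_fs"]
        )

    spikes = pd.read_csv(path / "spikes.tsv", sep="\t")
    _require_cols(spikes, ["unit_id", "spike_time_s"], "spikes.tsv")
    wf = pd.read_csv(path / "waveforms.csv")
    _require_cols(wf, ["unit_id", "channel", "sample_index", "uv"], "waveforms.csv")
    depths = pd.read_csv(path / "depths.csv")
    _require_cols(depths, ["unit_id", "depth_um"], "depths.csv")
    depth_map = dict(zip(depths["unit_id"].astype(str), depths["depth_um"]))

    units = []
    spikes["unit_id"] = spikes["unit_id"].astype(str)
    wf["unit_id"] = wf["unit_id"].astype(str)
    for uid, grp in wf.groupby("unit_id", sort=True):
        nc = int(grp["channel"].max()) + 1
        ns = int(grp["sample_index"].max()) + 1
        w = np.zeros((ns, nc))
        w[grp["sample_index"].to_numpy(), grp["channel"].to_numpy()] = grp["uv"].to_numpy()
        st = np.sort(spikes.loc[spikes["unit_id"] == uid, "spike_time_s"].to_numpy())
        units.append(
            SpikeUnit(
                unit_id=uid,
                spike_times=st,
                mean_waveform=w,
                depth_um=float(depth_map.get(uid, 0.0)),
                waveform_fs=float(meta.get("waveform_fs", 30000.0)),
            )
        )
    events = [InjectionEvent(e["drug"], e["time_min"]) for e in meta["events"]]
    return SessionRecording(
        session_id=meta["session_id"],
        group=meta["group"],
        hemisphere=meta["hemisphere"],
        lfp=lfp,
        lfp_fs=meta["lfp_fs"],
        imu=imu,
        units=units,
        events=events,
    )


def _require_cols(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise BundleError(f"{name}: missing columns {missing}")
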
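"""Neural–behavioural coupling analyses.

Three model objects, each built from data and fitted with :meth:`fit`:

* :class:`PowerSpeedCoupling` — per-frequency Pearson correlation between
  z-scored spectrogram power and frame-averaged inertial speed (the coupling
  spectrum);
* :class:`BandSpeedRegression` — OLS with every 0.5 Hz power bin of a band
  as predictor and speed as outcome, summarised by adjusted R²;
* :class:`TimescaleCoupling` — correlation between a unit's moving-average
  smoothed 5 ms firing-rate vector and inertial speed across smoothing
  windows from 50 ms to 4 s.

Results objects carry estimates, p-values and ``summary()`` frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, stats

from .io import SpeedSeries
from .preprocess import (
    ConditionWindow,
    bin_spike_counts,
    frame_average_speed,
    smooth_counts,
)
from .spectral import Spectrogram, zscore_power

log = logging.getLogger(__name__)

#: smoothing windows (ms) for the multi-timescale unit analysis
TIMESCALE_WINDOWS_MS = (
    50, 100, 150, 200, 250, 300, 400, 500, 800, 900,
    1000, 1250, 1500, 2000, 2500, 3000, 3500, 4000,
)


def pearson_with_p(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of ``x`` against each row of ``Y`` with two-sided t-test p."""
    x = np.asarray(x, dtype=np.float64)
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    n = x.size
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum() * (Yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc @ xc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(r)] = np.nan
    return r, p


def null_r_quantile(n: int, q: float = 0.95) -> float:
    """|r| quantile under the null for n paired observations (t-based)."""
    tq = stats.t.ppf(0.5 + q / 2.0, df=n - 2)
    return float(tq / np.sqrt(n - 2 + tq**2))


# ---------------------------------------------------------------------------
# coupling spectrum


@dataclass
class PowerSpeedCouplingResults:
    freqs: np.ndarray
    rvalues: np.ndarray
    pvalues: np.ndarray
    nobs: int
    condition: str | None = None
    constant_speed: bool = False

    def band_mean(self, band: tuple[float, float]) -> float:
        lo, hi = band
        m = (self.freqs >= lo - 1e-9) & (self.freqs <= hi + 1e-9)
        return float(np.nanmean(self.rvalues[m]))

    def holm_pvalues(self) -> np.ndarray:
        from .stats import holm_adjust

        return holm_adjust(self.pvalues)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_hz": self.freqs,
                "r": self.rvalues,
                "p": self.pvalues,
                "n": self.nobs,
                "condition": self.condition,
            }
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.freqs, self.rvalues)
        ax.axhline(0, color="k", lw=0.5)
        ax.set(xlabel="frequency (Hz)", ylabel="Pearson R vs inertial speed",
               title=self.condition or "")
        return ax


class PowerSpeedCoupling:
    """Per-frequency correlation between LFP power and inertial speed.

    Parameters
    ----------
    spectrogram
        Power on the 0.5 s × 0.5 Hz analysis grid for the window of
        interest; z-scored internally per frequency unless already z-scored.
    speed
        Full-session inertial speed at 200 Hz.
    window
        Analysis window; frames of the spectrogram are assumed to start at
        ``window.start_s``.
    """

    def __init__(
        self,
        spectrogram: Spectrogram,
        speed: SpeedSeries,
        window: tuple[float, float] | ConditionWindow,
        condition: str | None = None,
    ):
        self.spec = spectrogram if spectrogram.zscored else zscore_power(spectrogram)
        self.speed = speed
        self.window = window
        self.condition = condition or (
            window.label if isinstance(window, ConditionWindow) else None
        )

    def fit(self) -> PowerSpeedCouplingResults:
        n_frames = self.spec.n_frames
        if n_frames < 3:
            raise ValueError("need at least 3 frames for a coupling spectrum")
        sp = frame_average_speed(
            self.speed, self.window, self.spec.frame_s, self.spec.hop_s, n_frames
        )
        if np.nanstd(sp) == 0:
            log.warning("constant speed in window: coupling undefined")
            nanarr = np.full(self.spec.freqs.size, np.nan)
            return PowerSpeedCouplingResults(
                self.spec.freqs.copy(), nanarr, nanarr.copy(), n_frames,
                self.condition, constant_speed=True,
            )
        r, p = pearson_with_p(sp, self.spec.power)
        return PowerSpeedCouplingResults(
            self.spec.freqs.copy(), r, p, n_frames, self.condition
        )


# ---------------------------------------------------------------------------
# band regression


@dataclass
class BandSpeedRegressionResults:
    band: tuple[float, float]
    rsquared: float
    rsquared_adj: float
    params: pd.Series
    nobs: int
    n_predictors: int
    dropped_predictors: list = field(default_factory=list)
    condition: str | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "band": [f"{self.band[0]:g}-{self.band[1]:g} Hz"],
                "adj_r2": [self.rsquared_adj],
                "r2": [self.rsquared],
                "n_frames": [self.nobs],
                "n_predictors": [self.n_predictors],
                "condition": [self.condition],
            }
        )


class BandSpeedRegression:
    """OLS of frame-averaged speed on every z-scored power bin in a band.

    Adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1) summarises how much of the
    moment-to-moment speed the band's power explains.  Collinear predictors
    are dropped (QR pivot) with a log entry.
    """

    def __init__(
        self,
        spectrogram: Spectrogram,
        speed: SpeedSeries,
        band: tuple[float, float],
        window: tuple[float, float] | ConditionWindow,
        condition: str | None = None,
    ):
        self.spec = spectrogram if spectrogram.zscored else zscore_power(spectrogram)
        self.speed = speed
        self.band = band
        self.window = window
        self.condition = condition or (
            window.label if isinstance(window, ConditionWindow) else None
        )

    def fit(self) -> BandSpeedRegressionResults:
        mask = self.spec.band_mask(self.band)
        X = self.spec.power[mask].T  # frames × predictors
        freqs = self.spec.freqs[mask]
        n, p = X.shape
        if p == 0:
            raise ValueError(f"band {self.band} contains no frequency bins")
        if n < p + 2:
            raise ValueError(f"{n} frames insufficient for {p} predictors")
        y = frame_average_speed(
            self.speed, self.window, self.spec.frame_s, self.spec.hop_s, n
        )

        dropped: list[float] = []
        keep = np.arange(p)
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
            keep = np.sort(piv[:rank])
            dropped = [float(f) for f in freqs[np.sort(piv[rank:])]]
            log.warning("dropping %d collinear predictors", len(dropped))
            if keep.size == 0:
                raise ValueError("all predictors collinear")
        model = sm.OLS(y, sm.add_constant(X[:, keep]))
        res = model.fit()
        params = pd.Series(res.params[1:], index=freqs[keep], name="coef")
        return BandSpeedRegressionResults(
            band=self.band,
            rsquared=float(res.rsquared),
            rsquared_adj=float(res.rsquared_adj),
            params=params,
            nobs=n,
            n_predictors=int(keep.size),
            dropped_predictors=dropped,
            condition=self.condition,
        )


# ---------------------------------------------------------------------------
# unit × timescale coupling


@dataclass
class TimescaleCouplingResults:
    unit_id: str
    window_ms: np.ndarray
    rvalues: np.ndarray
    r2values: np.ndarray
    nobs: int
    condition: str | None = None
    silent: bool = False

    @property
    def mean_r2(self) -> float:
        """Unweighted mean R² across the configured smoothing windows."""
        return float(np.nanmean(self.r2values))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": self.unit_id,
                "window_ms": self.window_ms,
                "r": self.rvalues,
                "r2": self.r2values,
                "n": self.nobs,
                "condition": self.condition,
            }
        )


class TimescaleCoupling:
    """Unit firing ↔ speed correlation across smoothing timescales.

    Spikes are binned at 5 ms (one 200 Hz speed sample per bin), the count
    vector is moving-average smoothed at each window size, and the smoothed
    rate is correlated with the *unsmoothed* speed.
    """

    def __init__(
        self,
        spike_times: np.ndarray,
        speed: SpeedSeries,
        window: tuple[float, float] | ConditionWindow,
        window_sizes_ms: tuple = TIMESCALE_WINDOWS_MS,
        unit_id: str = "",
        condition: str | None = None,
        bin_ms: float = 5.0,
    ):
        self.spike_times = np.asarray(spike_times, dtype=np.float64)
        self.speed = speed
        self.window = window
        self.window_sizes_ms = tuple(window_sizes_ms)
        self.unit_id = unit_id
        self.bin_ms = bin_ms
        self.condition = condition or (
            window.label if isinstance(window, ConditionWindow) else None
        )

    def fit(self) -> TimescaleCouplingResults:
        if isinstance(self.window, ConditionWindow):
            start, end = self.window.start_s, self.window.end_s
        else:
            start, end = self.window
        if (end - start) * 1000.0 < max(self.window_sizes_ms):
            raise ValueError("window shorter than the largest smoothing window")
        counts = bin_spike_counts(self.spike_times, self.bin_ms / 1000.0, (start, end))
        sp = self.speed.slice(start, end)
        n = min(counts.size, sp.size)
        counts, sp = counts[:n].astype(float), sp[:n]
        ws = np.asarray(self.window_sizes_ms, dtype=float)
        if counts.sum() == 0:
            log.info("unit %s silent in window; flagged", self.unit_id)
            nanarr = np.full(ws.size, np.nan)
            return TimescaleCouplingResults(
                self.unit_id, ws, nanarr, nanarr.copy(), n, self.condition, silent=True
            )
        r = np.empty(ws.size)
        for i, w in enumerate(ws):
            smoothed = smooth_counts(counts, w, self.bin_ms)
            r[i] = pearson_with_p(sp, smoothed[None, :])[0][0]
        return TimescaleCouplingResults(
            self.unit_id, ws, r, r**2, n, self.condition
        )


def population_timescale_coupling(
    units,
    speed: SpeedSeries,
    window,
    condition: str | None = None,
    window_sizes_ms: tuple = TIMESCALE_WINDOWS_MS,
) -> pd.DataFrame:
    """Per-unit timescale curves for a population, silent units flagged.

    Returns a long-form frame (unit_id, window_ms, r, r2, condition, silent);
    aggregate with ``groupby`` for the per-animal grain (mean R² across
    windows, then across units).
    """
    frames = []
    for u in units:
        res = TimescaleCoupling(
            u.spike_times, speed, window, window_sizes_ms,
            unit_id=u.unit_id, condition=condition,
        ).fit()
        df = res.summary()
        df["silent"] = res.silent
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
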
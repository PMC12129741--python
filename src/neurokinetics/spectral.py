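"""LFP spectral decomposition: STFT spectrograms, z-scoring, IRASA.

The spectrogram grid is fixed by the analysis design: 1 s Hann frames with
0.5 s hop, one-sided PSD on a 0.5 Hz grid restricted to 1–120 Hz (239 bins).
IRASA separates the aperiodic 1/f (fractal) component from narrowband
oscillations by irregular resampling: a fractal spectrum is self-similar
under resampling by h and 1/h while an oscillatory peak is displaced, so the
median across resampling factors of the geometric-mean PSD estimates the
fractal part and the residual is the oscillatory spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

log = logging.getLogger(__name__)

#: default IRASA resampling factors (1.1 … 1.9 in steps of 0.05)
DEFAULT_HSET = tuple(np.round(np.arange(1.1, 1.9 + 1e-9, 0.05), 2))


@dataclass
class Spectrogram:
    """Time × frequency power, frames on the rows of ``power.T`` convention:
    ``power`` is (n_freqs, n_frames), µV²/Hz."""

    power: np.ndarray
    freqs: np.ndarray
    frame_times: np.ndarray  # frame start times, s, relative to the input
    frame_s: float = 1.0
    hop_s: float = 0.5
    zscored: bool = False

    @property
    def n_frames(self) -> int:
        return self.power.shape[1]

    def band_mask(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        return (self.freqs >= lo - 1e-9) & (self.freqs <= hi + 1e-9)


@dataclass
class IrasaSpectrum:
    freqs: np.ndarray
    total: np.ndarray
    fractal: np.ndarray
    hset: tuple = DEFAULT_HSET
    negative_residual_frac: float = field(init=False)

    def __post_init__(self) -> None:
        osc = self.total - self.fractal
        self.negative_residual_frac = float(np.mean(osc < 0))

    @property
    def oscillatory(self) -> np.ndarray:
        """Residual total − fractal; may be negative where the fractal fit
        overshoots (flagged via ``negative_residual_frac``)."""
        return self.total - self.fractal


def compute_spectrogram(
    lfp: np.ndarray,
    fs: float = 500.0,
    fmin: float = 1.0,
    fmax: float = 120.0,
    frame_s: float = 1.0,
    hop_s: float = 0.5,
    df: float = 0.5,
) -> Spectrogram:
    """Hann-tapered STFT power spectrogram on the analysis grid.

    Frames are zero-padded so the frequency spacing is ``df`` regardless of
    the frame length (500-sample frames → nfft 1000 for 0.5 Hz bins).
    """
    lfp = np.asarray(lfp, dtype=np.float64)
    if fs != 500.0:
        raise ValueError(
            f"spectrogram expects 500 Hz LFP, got {fs:g} Hz; downsample first"
        )
    nperseg = int(round(frame_s * fs))
    hop = int(round(hop_s * fs))
    nfft = int(round(fs / df))
    if lfp.size < nperseg:
        raise ValueError("LFP shorter than one frame")
    freqs, times, sxx = signal.spectrogram(
        lfp,
        fs=fs,
        window=signal.get_window("hann", nperseg),
        nperseg=nperseg,
        noverlap=nperseg - hop,
        nfft=nfft,
        detrend=False,
        mode="psd",
    )
    mask = (freqs >= fmin - 1e-9) & (freqs <= fmax + 1e-9)
    frame_starts = times - frame_s / 2.0
    return Spectrogram(
        power=sxx[mask],
        freqs=freqs[mask],
        frame_times=frame_starts,
        frame_s=frame_s,
        hop_s=hop_s,
    )


def zscore_power(spec: Spectrogram) -> Spectrogram:
    """Per-frequency z-score across frames; zero-variance rows become 0."""
    if spec.n_frames < 2:
        raise ValueError("need at least 2 frames to z-score")
    mu = spec.power.mean(axis=1, keepdims=True)
    sd = spec.power.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    if np.any(flat):
        log.warning("%d zero-variance frequency rows set to z=0", int(flat.sum()))
        sd[flat] = 1.0
    z = (spec.power - mu) / sd
    z[flat] = 0.0
    return Spectrogram(
        power=z,
        freqs=spec.freqs.copy(),
        frame_times=spec.frame_times.copy(),
        frame_s=spec.frame_s,
        hop_s=spec.hop_s,
        zscored=True,
    )


def compute_irasa(
    lfp: np.ndarray,
    fs: float = 500.0,
    fmin: float = 1.0,
    fmax: float = 120.0,
    hset: tuple = DEFAULT_HSET,
    seg_s: float = 4.0,
) -> IrasaSpectrum:
    """Irregular-resampling auto-spectral decomposition of an LFP window.

    For each resampling factor h the signal is resampled by h and by 1/h
    (polyphase, rational approximation of h), the Welch PSD of each is taken
    on the original frequency grid, and their geometric mean retains the
    fractal component while displacing oscillatory peaks.  The fractal PSD is
    the median of these geometric means across ``hset``.
    """
    lfp = np.asarray(lfp, dtype=np.float64)
    if any(h <= 1 for h in hset):
        raise ValueError("IRASA resampling factors must be > 1")
    if lfp.size < 20 * fs:
        log.info("IRASA window of %.1f s is shorter than the recommended 20 s",
                 lfp.size / fs)
    nperseg = int(round(seg_s * fs))

    def welch(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return signal.welch(
            x, fs=fs, window="hann", nperseg=nperseg,
            noverlap=nperseg // 2, detrend="constant",
        )

    freqs, total = welch(lfp)
    geomeans = np.empty((len(hset), freqs.size))
    for i, h in enumerate(hset):
        frac = Fraction(h).limit_denominator(100)
        up = signal.resample_poly(lfp, frac.numerator, frac.denominator)
        down = signal.resample_poly(lfp, frac.denominator, frac.numerator)
        _, p_up = welch(up)
        _, p_down = welch(down)
        geomeans[i] = np.sqrt(p_up * p_down)
    fractal = np.median(geomeans, axis=0)
    mask = (freqs >= fmin - 1e-9) & (freqs <= fmax + 1e-9)
    return IrasaSpectrum(
        freqs=freqs[mask], total=total[mask], fractal=fractal[mask], hset=tuple(hset)
    )


def oscillatory_band_power(irasa: IrasaSpectrum, band: tuple[float, float]) -> float:
    """Mean oscillatory PSD over a band, negative residuals floored at 0."""
    lo, hi = band
    mask = (irasa.freqs >= lo - 1e-9) & (irasa.freqs <= hi + 1e-9)
    if not np.any(mask):
        raise ValueError(f"band {band} outside the frequency grid")
    osc = irasa.oscillatory[mask]
    n_neg = int(np.sum(osc < 0))
    if n_neg:
        log.info("flooring %d negative oscillatory bins in band %s", n_neg, band)
    return float(np.mean(np.maximum(osc, 0.0)))


def oscillatory_peaks(
    irasa: IrasaSpectrum, min_prominence_frac: float = 0.1
) -> np.ndarray:
    """Frequencies of oscillatory peaks, ordered by height.

    Prominence threshold is a fraction of the tallest oscillatory value, so
    that genuinely bimodal spectra report both modes.
    """
    osc = np.maximum(irasa.oscillatory, 0.0)
    if osc.max() <= 0:
        return np.array([])
    idx, _ = signal.find_peaks(osc, prominence=min_prominence_frac * osc.max())
    order = np.argsort(osc[idx])[::-1]
    return irasa.freqs[idx[order]]


# default analysis bands (Hz); edges configurable at call sites
BANDS = {
    "beta": (15.0, 30.0),
    "gamma": (35.0, 120.0),
    "ftg": (75.0, 85.0),
    "ketamine-gamma": (45.0, 55.0),
}
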
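"""Neural ensemble structure: cell-pair correlations, state similarity and
pair-correlation change across drug states.

The state-similarity measure correlates two states' vectors of cell-pair
spike-count correlations (akin to the explained-variance reactivation
measure): values near 1 mean the between-neuron correlation pattern is
preserved, near 0 that the ensemble has reconfigured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ConditionWindow, bin_spike_counts

log = logging.getLogger(__name__)


@dataclass
class PairCorrelationSet:
    """Pairwise spike-count Pearson correlations in one state.

    ``pairs`` columns: unit_i, unit_j (i < j), r, p, n, missing (a pair is
    missing if either unit was silent throughout the window).
    """

    state: str
    bin_s: float
    pairs: pd.DataFrame
    session_id: str = ""

    @property
    def valid(self) -> pd.DataFrame:
        return self.pairs.loc[~self.pairs["missing"]]


@dataclass
class StateSimilarity:
    state_a: str
    state_b: str
    similarity: float
    n_pairs: int
    low_confidence: bool = False


@dataclass
class PairDeltaResult:
    """Change in cell-pair correlations from a pre to a post state."""

    deltas: pd.DataFrame  # unit_i, unit_j, r_pre, r_post, delta, abs_delta
    mean_delta: float
    median_delta: float
    mean_abs_delta: float
    wilcoxon_p: float
    n_pairs: int
    alpha: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_pairs": [self.n_pairs],
                "mean_delta": [self.mean_delta],
                "median_delta": [self.median_delta],
                "mean_abs_delta": [self.mean_abs_delta],
                "wilcoxon_p": [self.wilcoxon_p],
                "alpha": [self.alpha],
            }
        )


def pairwise_correlations(
    units,
    window: tuple[float, float] | ConditionWindow,
    bin_s: float = 1.0,
    state: str | None = None,
    session_id: str = "",
) -> PairCorrelationSet:
    """Pearson correlation of binned spike counts for every unit pair."""
    if len(units) < 2:
        raise ValueError("need at least 2 units for pair correlations")
    label = state or (window.label if isinstance(window, ConditionWindow) else "")
    counts = np.vstack(
        [bin_spike_counts(u.spike_times, bin_s, window) for u in units]
    ).astype(np.float64)
    n_units, n_bins = counts.shape
    if n_bins < 100:
        log.info("only %d bins in window; pair correlations are noisy", n_bins)
    silent = counts.sum(axis=1) == 0

    sd = counts.std(axis=1)
    sd_safe = np.where(sd == 0, 1.0, sd)
    zc = (counts - counts.mean(axis=1, keepdims=True)) / sd_safe[:, None]
    R = (zc @ zc.T) / n_bins
    np.clip(R, -1.0, 1.0, out=R)

    rows = []
    for i in range(n_units):
        for j in range(i + 1, n_units):
            missing = bool(silent[i] or silent[j] or sd[i] == 0 or sd[j] == 0)
            r = np.nan if missing else R[i, j]
            if missing or abs(r) == 1.0:
                p = np.nan if missing else 0.0
            else:
                t = r * np.sqrt((n_bins - 2) / (1.0 - r**2))
                p = 2.0 * stats.t.sf(abs(t), df=n_bins - 2)
            rows.append((units[i].unit_id, units[j].unit_id, r, p, n_bins, missing))
    pairs = pd.DataFrame(
        rows, columns=["unit_i", "unit_j", "r", "p", "n", "missing"]
    )
    return PairCorrelationSet(state=label, bin_s=bin_s, pairs=pairs, session_id=session_id)


def _matched(setA: PairCorrelationSet, setB: PairCorrelationSet) -> pd.DataFrame:
    a = setA.valid.set_index(["unit_i", "unit_j"])
    b = setB.valid.set_index(["unit_i", "unit_j"])
    m = a.join(b, how="inner", lsuffix="_a", rsuffix="_b")
    return m.reset_index()


def state_similarity(setA: PairCorrelationSet, setB: PairCorrelationSet) -> StateSimilarity:
    """Pearson correlation between two states' pair-correlation vectors.

    Symmetric in its arguments; pairs flagged missing in either state are
    dropped pairwise.  Fewer than 10 shared pairs → flagged low-confidence.
    """
    if setA.session_id != setB.session_id:
        raise ValueError("state similarity is defined within a session")
    m = _matched(setA, setB)
    n = len(m)
    if n == 0:
        raise ValueError("no shared valid pairs between states")
    if np.std(m["r_a"]) == 0 or np.std(m["r_b"]) == 0:
        sim = np.nan
        log.warning("degenerate pair-correlation vector; similarity undefined")
    else:
        sim = float(np.corrcoef(m["r_a"], m["r_b"])[0, 1])
    return StateSimilarity(
        state_a=setA.state,
        state_b=setB.state,
        similarity=sim,
        n_pairs=n,
        low_confidence=n < 10,
    )


def pair_correlation_change(
    set_pre: PairCorrelationSet,
    set_post: PairCorrelationSet,
    alpha: float = 0.05,
) -> PairDeltaResult:
    """Signed and absolute change in cell-pair correlations pre → post.

    Only pairs whose correlation is significant (p ≤ alpha, uncorrected) in
    the pre *or* post state are retained, so correlations that appear and
    correlations that disappear both count.  The Wilcoxon signed-rank test
    assesses a median shift of the signed change.
    """
    m = _matched(set_pre, set_post)
    sig = (m["p_a"] <= alpha) | (m["p_b"] <= alpha)
    m = m.loc[sig].copy()
    if m.empty:
        raise ValueError(
            f"no significant pairs at alpha={alpha} "
            f"({len(sig)} matched pairs before filtering)"
        )
    m["delta"] = m["r_b"] - m["r_a"]
    m["abs_delta"] = m["delta"].abs()
    d = m["delta"].to_numpy()
    if np.allclose(d, 0.0):
        wp = np.nan
        log.info("all pair deltas are zero; signed-rank test undefined")
    else:
        wp = float(stats.wilcoxon(d, zero_method="wilcox").pvalue)
    out = m.rename(columns={"r_a": "r_pre", "r_b": "r_post"})[
        ["unit_i", "unit_j", "r_pre", "r_post", "delta", "abs_delta"]
    ]
    return PairDeltaResult(
        deltas=out.reset_index(drop=True),
        mean_delta=float(np.mean(d)),
        median_delta=float(np.median(d)),
        mean_abs_delta=float(np.mean(np.abs(d))),
        wilcoxon_p=wp,
        n_pairs=len(m),
        alpha=alpha,
    )
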
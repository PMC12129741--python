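"""Statistical harness: the a-priori sample-size calculation and
multiple-comparison adjustment used by the pipeline reports."""

from __future__ import annotations

import numpy as np
from scipy import stats


def t_test_power(
    effect_size: float, n: int, alpha: float = 0.05, tails: int = 2,
    two_sample: bool = False,
) -> float:
    """Power of a one-sample (or paired) t-test at standardized effect size d.

    Uses the noncentral-t distribution: ncp = d·√n (one-sample) or
    d·√(n/2) (two-sample, per-group n), critical value from the central t.
    """
    if two_sample:
        df = 2 * n - 2
        ncp = effect_size * np.sqrt(n / 2.0)
    else:
        df = n - 1
        ncp = effect_size * np.sqrt(n)
    if df < 1:
        return 0.0
    a = alpha / tails
    tcrit = stats.t.ppf(1.0 - a, df)
    power = stats.nct.sf(tcrit, df, ncp)
    if tails == 2:
        power += stats.nct.cdf(-tcrit, df, ncp)
    return float(power)


def sample_size_t(
    mu0: float,
    sd: float,
    reduction_fraction: float,
    alpha: float = 0.05,
    power: float = 0.8,
    tails: int = 2,
    two_sample: bool = False,
    n_max: int = 10**6,
) -> int:
    """Smallest n detecting a ``reduction_fraction`` drop from ``mu0``.

    The alternative mean is mu0·(1 − reduction_fraction); the standardized
    effect size is |mu0·reduction_fraction| / sd.  Matches the one-sample
    noncentral-t construction of standard power calculators.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not 0 < reduction_fraction <= 1:
        raise ValueError("reduction_fraction must be in (0, 1]")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    d = abs(mu0 * reduction_fraction) / sd
    for n in range(2, n_max + 1):
        if t_test_power(d, n, alpha, tails, two_sample) >= power:
            return n
    raise ValueError(f"target power unreachable within n ≤ {n_max}")


def monte_carlo_power(
    mu0: float,
    sd: float,
    reduction_fraction: float,
    n: int,
    alpha: float = 0.05,
    n_sim: int = 100_000,
    seed: int = 0,
) -> float:
    """Simulated one-sample two-tailed t-test power — the independent check
    on :func:`sample_size_t` (tests H0: mean = mu0 on N(mu1, sd) samples)."""
    rng = np.random.default_rng(seed)
    mu1 = mu0 * (1.0 - reduction_fraction)
    x = rng.normal(mu1, sd, size=(n_sim, n))
    se = x.std(axis=1, ddof=1) / np.sqrt(n)
    t = (x.mean(axis=1) - mu0) / se
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, n - 1)
    return float(np.mean(np.abs(t) > tcrit))


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Bonferroni–Holm step-down adjusted p-values.

    Sorted ascending, p(i) is multiplied by (m − i), cumulative-maxed so the
    adjusted sequence is monotone, and capped at 1.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p)
    adj = p[order] * (m - np.arange(m))
    adj = np.maximum.accumulate(adj)
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out
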
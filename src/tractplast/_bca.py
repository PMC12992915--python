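"""Bias-corrected and accelerated (BCa) bootstrap intervals."""

from __future__ import annotations

import numpy as np
from scipy import stats


def bca_interval(theta_hat: float, boot: np.ndarray, jack: np.ndarray,
                 alpha: float = 0.05) -> tuple[float, float]:
    """BCa confidence interval for one statistic.

    ``boot`` are bootstrap replicates of the statistic, ``jack`` the
    leave-one-subject-out jackknife values used for the acceleration
    constant.  Degenerate distributions collapse to a point interval;
    when the bias correction is undefined (all replicates on one side of
    the point estimate) the interval falls back to plain percentiles.
    """
    boot = np.asarray(boot, dtype=float)
    boot = boot[np.isfinite(boot)]
    if boot.size == 0:
        return (np.nan, np.nan)
    if np.ptp(boot) == 0:
        return (float(boot[0]), float(boot[0]))
    # bias correction; half-weight ties for continuity
    prop = np.mean(boot < theta_hat) + 0.5 * np.mean(boot == theta_hat)
    if not 0.0 < prop < 1.0:
        lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return (float(lo), float(hi))
    z0 = stats.norm.ppf(prop)
    # acceleration from the jackknife skewness
    jack = np.asarray(jack, dtype=float)
    jack = jack[np.isfinite(jack)]
    a = 0.0
    if jack.size >= 3:
        d = jack.mean() - jack
        denom = (d ** 2).sum() ** 1.5
        if denom > 0:
            a = (d ** 3).sum() / (6.0 * denom)
    out = []
    for q in (alpha / 2, 1 - alpha / 2):
        zq = stats.norm.ppf(q)
        adj = z0 + (z0 + zq) / (1.0 - a * (z0 + zq))
        out.append(float(np.percentile(boot, 100 * stats.norm.cdf(adj))))
    return (out[0], out[1])
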
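"""Linking latent microstructural change to motor learning.

Per-segment PC1 change scores over the two learning-relevant intervals
(baseline to post-training, and control-end to post-training) are rank-
correlated with per-subject learning exponents.  The two interval
correlations are combined by fixed-effect meta-analysis using the
Olkin-Pratt unbiased correction

    G_i = r_i * (1 + (1 - r_i^2) / (2 * (n_i - 3)))

with sample-size weights, and normal-approximation confidence intervals
and p-values from the per-study variance ``(1 - G^2)^2 / (n_i - 1)``.
One-sided p-values follow the hypothesized direction of the effect (the
sign of the group PC1 trajectory change); the two intervals share the
post-training session and are therefore not independent — the pooled
interval is mildly anti-conservative, as in fixed-effect pooling of
dependent correlations generally.

Before correlation, adjacent plastic segments with similar PC1 loading
structure (pairwise cosine >= 0.9 by default) are merged: their raw metric
values are averaged per (subject, session, metric) and the segment model
is refitted on the averaged profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .asca import SegmentASCA
from .panel import TractProfilePanel

logger = logging.getLogger(__name__)

__all__ = [
    "PooledCorrelation", "merge_adjacent_segments", "interval_change_scores",
    "spearman", "pool_point_estimate", "pooled_ci_p", "pooled_correlation",
]


# ------------------------------------------------------------------ merging

def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(abs(u @ v) / (nu * nv))


def merge_adjacent_segments(results: dict[int, "object"],
                            panel: TractProfilePanel, tract: str,
                            cosine_min: float = 0.9,
                            B: int = 1000, seed: int | None = None) -> list[dict]:
    """Merge runs of adjacent plastic segments with similar loadings.

    ``results`` maps segment index to a fitted :class:`SegmentASCAResults`.
    Maximal runs of consecutive plastic segments whose PC1 loadings have
    pairwise |cosine| >= ``cosine_min`` form one group; the group's raw
    metric values are averaged across segments and the model refitted on
    the averaged data.  Returns a list of dicts with keys ``segments``,
    ``label`` and ``model``.
    """
    plastic = sorted(s for s, r in results.items() if r.plastic)
    groups: list[list[int]] = []
    for s in plastic:
        if groups and s == groups[-1][-1] + 1:
            cand = groups[-1] + [s]
            load_s = results[s].loadings.iloc[:, 0].to_numpy()
            ok = all(_cosine(load_s,
                             results[t].loadings.iloc[:, 0].to_numpy())
                     >= cosine_min for t in groups[-1])
            if ok:
                groups[-1] = cand
                continue
        groups.append([s])
    merged = []
    for grp in groups:
        label = f"{grp[0]}" if len(grp) == 1 else f"{grp[0]}-{grp[-1]}"
        df = panel.data
        sub = df[(df["tract"] == tract) & (df["segment"].isin(grp))]
        avg = (sub.groupby(["subject_id", "session", "metric"], as_index=False)
               ["value"].mean())
        avg["tract"] = tract
        avg["segment"] = grp[0]
        mpanel = TractProfilePanel(avg, session_order=panel.session_order,
                                   validate=False)
        model = SegmentASCA(mpanel, tract, grp[0]).fit(B=B, seed=seed)
        merged.append({"segments": tuple(grp), "label": label, "model": model})
    return merged


# --------------------------------------------------------------- change link

def interval_change_scores(subject_scores: pd.DataFrame) -> pd.DataFrame:
    """Per-subject interval changes of PC1 scores.

    ``subject_scores`` is (subjects x sessions), ordered baseline,
    control-end, post-training.  Returns columns ``delta_13`` and
    ``delta_23``; subjects with a missing session score are excluded from
    the affected interval (logged).
    """
    if subject_scores.shape[1] != 3:
        raise ValueError("expect scores at exactly 3 sessions")
    s1, s2, s3 = (subject_scores.iloc[:, j] for j in range(3))
    out = pd.DataFrame({"delta_13": s3 - s1, "delta_23": s3 - s2})
    n_miss = int(out.isna().any(axis=1).sum())
    if n_miss:
        logger.warning("%d subjects missing an interval change score", n_miss)
    return out


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Zero-variance input is undefined and reported as NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("need n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero-variance input: Spearman undefined")
        return np.nan
    return float(stats.spearmanr(x, y).statistic)


# ------------------------------------------------------------------- pooling

def pool_point_estimate(r_list, n_list) -> float:
    """Olkin-Pratt pooled correlation (first-order unbiased correction,
    sample-size weights)."""
    r = np.asarray(r_list, dtype=float)
    n = np.asarray(n_list, dtype=float)
    if len(r) != len(n) or len(r) == 0:
        raise ValueError("r_list and n_list must be equal-length, non-empty")
    if np.any(n <= 4):
        raise ValueError("each n must exceed 4")
    G = np.empty_like(r)
    degenerate = np.abs(r) >= 1.0
    if degenerate.any():
        warnings.warn("|r| = 1: unbiased correction degenerate, passing "
                      "through", stacklevel=2)
        G[degenerate] = r[degenerate]
    ok = ~degenerate
    G[ok] = r[ok] * (1.0 + (1.0 - r[ok] ** 2) / (2.0 * (n[ok] - 3.0)))
    return float(np.sum(n * G) / np.sum(n))


@dataclass
class PooledCorrelation:
    """Pooled brain-behavior correlation for one tract section."""

    r_13: float
    r_23: float
    G_pooled: float
    ci_low: float
    ci_high: float
    p_one_sided: float
    p_two_sided: float
    n_list: tuple[int, ...]
    direction: int                     # hypothesized sign (+1 / -1)

    def summary(self) -> str:
        return (f"G(r) = {self.G_pooled:+.2f}, 95% CI [{self.ci_low:.2f}, "
                f"{self.ci_high:.2f}], one-sided p = {self.p_one_sided:.3g} "
                f"(two-sided {self.p_two_sided:.3g}); "
                f"r13 = {self.r_13:+.2f}, r23 = {self.r_23:+.2f}, "
                f"n = {self.n_list}")


def pooled_ci_p(G_pooled: float, n_list, direction: int = -1,
                ci_level: float = 0.95):
    """Normal-approximation CI and p-values for a pooled correlation.

    Per-study variance ``v_i = (1 - G^2)^2 / (n_i - 1)`` with weights
    ``w_i = n_i``; pooled variance ``V = sum(w^2 v) / (sum w)^2``.  The
    one-sided p is taken in the hypothesized ``direction``.
    """
    if not abs(G_pooled) < 1:
        raise ValueError("|G| must be < 1")
    n = np.asarray(n_list, dtype=float)
    if np.any(n <= 1):
        raise ValueError("each n must exceed 1")
    v = (1.0 - G_pooled ** 2) ** 2 / (n - 1.0)
    V = float(np.sum(n ** 2 * v) / np.sum(n) ** 2)
    se = np.sqrt(V)
    zcrit = stats.norm.ppf(0.5 + ci_level / 2)
    lo, hi = G_pooled - zcrit * se, G_pooled + zcrit * se
    z = G_pooled / se
    p_two = 2.0 * stats.norm.sf(abs(z))
    p_one = stats.norm.cdf(z) if direction < 0 else stats.norm.sf(z)
    return float(lo), float(hi), float(p_one), float(min(p_two, 1.0))


def pooled_correlation(delta_scores: pd.DataFrame, learning_rates: pd.Series,
                       direction: int | None = None) -> PooledCorrelation:
    """Pool the two interval rank correlations for one tract section.

    ``delta_scores`` has columns delta_13 and delta_23 indexed by subject;
    ``learning_rates`` are the per-subject power-law exponents.  If
    ``direction`` is None, the hypothesized sign is the sign of the mean
    interval change (the group PC1 trajectory), fixed before computing p.
    """
    lr = learning_rates.reindex(delta_scores.index)
    rs, ns = [], []
    for col in ("delta_13", "delta_23"):
        d = delta_scores[col]
        ok = d.notna() & lr.notna()
        rs.append(spearman(d[ok], lr[ok]))
        ns.append(int(ok.sum()))
    if direction is None:
        mean_change = float(np.nanmean(delta_scores.to_numpy()))
        direction = -1 if mean_change < 0 else 1
    G = pool_point_estimate(rs, ns)
    lo, hi, p1, p2 = pooled_ci_p(G, ns, direction=direction)
    return PooledCorrelation(r_13=rs[0], r_23=rs[1], G_pooled=G,
                             ci_low=lo, ci_high=hi, p_one_sided=p1,
                             p_two_sided=p2, n_list=tuple(ns),
                             direction=direction)
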
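"""Monte Carlo familywise null for the four-criterion segment selection.

A tract segment counts as behaviorally relevant plasticity only when four
criteria hold simultaneously (stable control interval, change over both
learning intervals, and behavioral correlation).  Under the null, each
segment's four criteria are modelled as equicorrelated standard-normal
z-scores (pairwise correlation rho, one-factor construction

    z_j = sqrt(rho) * W + sqrt(1 - rho) * eps_j,

exact for uniform rho and unit marginal variance).  A segment is a false
positive when the least extreme of its k z-scores exceeds the threshold in
absolute value, i.e. all k do — deliberately conservative in that the
non-significance requirement of the control criterion is treated as a
fourth significance criterion.  The Monte Carlo p-value is the proportion
of simulated datasets whose false-positive count reaches the empirically
observed count (no continuity correction).

A semi-analytic cross-check integrates the per-segment pass probability
over the shared factor (1-D Gauss quadrature), under which the count is
exactly Binomial(n_segments, q).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from .exceptions import ConfigurationError

__all__ = ["McConfig", "McResult", "run_null_simulation",
           "analytic_pass_probability", "analytic_p_value"]


@dataclass
class McConfig:
    """Null-model parameters (defaults match the study design we emulate:
    2,320 segments = 29 tracts x 80 segments, four criteria, rho = 0.5,
    |z| > 1.96, nine observed segments, 10,000 iterations)."""

    n_iter: int = 10_000
    n_segments: int = 2_320
    k: int = 4
    rho: float = 0.5
    z_thresh: float = 1.96
    observed: int = 9
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ConfigurationError("rho must lie in [0, 1)")
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.z_thresh <= 0:
            raise ConfigurationError("z_thresh must be > 0")
        if self.observed < 0:
            raise ConfigurationError("observed must be >= 0")
        if self.n_iter < 1 or self.n_segments < 1:
            raise ConfigurationError("n_iter and n_segments must be >= 1")


@dataclass
class McResult:
    counts: np.ndarray                 # false positives per iteration
    monte_carlo_p: float
    config: McConfig
    histogram: dict[int, int] = field(default_factory=dict)

    def summary(self) -> str:
        c = self.config
        return (f"Monte Carlo null: {c.n_iter} iterations x {c.n_segments} "
                f"segments, k={c.k}, rho={c.rho}, |z|>{c.z_thresh}\n"
                f"  mean count {self.counts.mean():.2f}, "
                f"P(count >= {c.observed}) = {self.monte_carlo_p:.4f}")


def run_null_simulation(config: McConfig | None = None,
                        rng: np.random.Generator | None = None,
                        chunk: int = 250) -> McResult:
    """Vectorized simulation of the equicorrelated null model."""
    if config is None:
        config = McConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    a, b = np.sqrt(config.rho), np.sqrt(1.0 - config.rho)
    counts = np.empty(config.n_iter, dtype=np.int64)
    done = 0
    while done < config.n_iter:
        m = min(chunk, config.n_iter - done)
        w = rng.standard_normal((m, config.n_segments, 1))
        z = a * w + b * rng.standard_normal((m, config.n_segments, config.k))
        retained = np.abs(z).min(axis=2)       # least extreme of the k scores
        counts[done:done + m] = (retained > config.z_thresh).sum(axis=1)
        done += m
    p = float(np.mean(counts >= config.observed))
    hist = {int(v): int(c) for v, c in zip(*np.unique(counts, return_counts=True))}
    return McResult(counts=counts, monte_carlo_p=p, config=config,
                    histogram=hist)


def analytic_pass_probability(k: int = 4, rho: float = 0.5,
                              z_thresh: float = 1.96) -> float:
    """Per-segment probability that all k |z| exceed the threshold.

    Integrates the conditional exceedance probability over the shared
    factor; for ``rho = 0`` this reduces to ``(2*Phi(-z))**k``.
    """
    if rho == 0.0:
        return float((2 * stats.norm.sf(z_thresh)) ** k)
    a, b = np.sqrt(rho), np.sqrt(1.0 - rho)

    def integrand(w):
        p = (stats.norm.sf((z_thresh - a * w) / b)
             + stats.norm.cdf((-z_thresh - a * w) / b))
        return p ** k * stats.norm.pdf(w)

    q, _ = integrate.quad(integrand, -12, 12, limit=200)
    return float(q)


def analytic_p_value(config: McConfig | None = None) -> float:
    """Binomial tail P(count >= observed) under the semi-analytic null."""
    if config is None:
        config = McConfig()
    q = analytic_pass_probability(config.k, config.rho, config.z_thresh)
    if config.observed == 0:
        return 1.0
    return float(stats.binom.sf(config.observed - 1, config.n_segments, q))
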
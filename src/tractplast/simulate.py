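"""Synthetic cohort generator for along-tract plasticity analyses.

Generates tract-profile panels, balance-task behavior, and cortical change
scores with the longitudinal structure the downstream analysis assumes:

* metric value = native mean + native scale * (subject intercept
  + training effect + AR(1)-correlated residual along segments);
* training effects are zero at baseline and during the control interval,
  and load a signed unit-norm metric pattern at configured segments at the
  post-training session;
* per-trial balance times follow subject-specific power laws whose
  exponents are rank-correlated (Gaussian copula) with the subjects'
  latent white-matter effect magnitudes;
* the cortical change score is a noisy linear function of the same
  magnitudes.

Randomness: one master seed; child seeds for the profile, behavior and
cortical components are spawned deterministically and recorded on the
returned :class:`SyntheticCohort`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import METRIC_BASELINES, CohortConfig
from .panel import TractProfilePanel

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticCohort",
    "generate_tract_profiles",
    "generate_behavior",
    "generate_cortical_response",
    "simulate_cohort",
]


@dataclass
class SyntheticCohort:
    """Bundle of all generated tables plus the latent ground truth."""

    panel: TractProfilePanel
    behavior: pd.DataFrame
    cortical: pd.DataFrame
    magnitudes: np.ndarray          # per-subject magnitude of the first effect
    exponents: np.ndarray           # per-subject learning exponents b_i
    child_seeds: dict[str, int] = field(default_factory=dict)


def _metric_baseline(metric: str) -> tuple[float, float]:
    # unknown (user-added) metrics default to a unit z-scale
    return METRIC_BASELINES.get(metric, (0.0, 1.0))


def _ar1_field(rng: np.random.Generator, shape: tuple[int, ...],
               n_segments: int, phi: float, sigma: float) -> np.ndarray:
    """Stationary AR(1) noise along the last-but-one axis (segments)."""
    out = np.empty(shape + (n_segments,))
    innov = rng.standard_normal(shape + (n_segments,))
    out[..., 0] = innov[..., 0]
    scale = np.sqrt(1.0 - phi * phi)
    for s in range(1, n_segments):
        out[..., s] = phi * out[..., s - 1] + scale * innov[..., s]
    return sigma * out


def generate_tract_profiles(config: CohortConfig,
                            rng: np.random.Generator | None = None
                            ) -> tuple[TractProfilePanel, np.ndarray]:
    """Generate the balanced tract-profile panel.

    Returns the panel and the per-subject magnitudes ``m_i`` of the first
    effect template (zeros when no effects are configured), for use as the
    ground truth in oracle tests and as the coupling variable for the
    behavioral and cortical generators.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_sub = config.n_subjects
    n_sess = len(config.sessions)
    n_seg = config.n_segments
    metrics = config.metrics
    n_met = len(metrics)
    subjects = [f"S{i + 1:02d}" for i in range(n_sub)]

    # shared latent plasticity factor across effect templates
    latent = rng.standard_normal(n_sub)
    u = rng.standard_normal((n_sub, n_met)) * config.sigma_subject

    frames = []
    magnitudes = np.zeros(n_sub)
    met_idx = {m: k for k, m in enumerate(metrics)}
    sess_idx = {s: j for j, s in enumerate(config.sessions)}

    for tract in config.tracts:
        # z-scale signal: subject intercept + effect + AR(1) noise
        z = np.zeros((n_sub, n_sess, n_met, n_seg))
        z += u[:, None, :, None]
        if config.sigma_resid > 0:
            z += _ar1_field(rng, (n_sub, n_sess, n_met), n_seg,
                            config.ar_phi, config.sigma_resid)
        for e_i, eff in enumerate(config.effects):
            if eff.tract != tract:
                continue
            m_i = eff.group_magnitude + eff.subject_sd * latent
            if e_i == 0:
                magnitudes = m_i
            segs = [s - 1 for s in eff.segments]
            for metric, w in eff.loading_pattern.items():
                k = met_idx[metric]
                if len(config.sessions) >= 3:
                    for s0 in segs:
                        z[:, sess_idx[config.sessions[2]], k, s0] += w * m_i
                if len(config.sessions) >= 2 and eff.control_magnitude != 0.0:
                    for s0 in segs:
                        z[:, sess_idx[config.sessions[1]], k, s0] += (
                            w * eff.control_magnitude)
        # map to native units and flatten
        for k, metric in enumerate(metrics):
            mu, scale = _metric_baseline(metric)
            vals = mu + scale * z[:, :, k, :]
            frames.append(pd.DataFrame({
                "subject_id": np.repeat(subjects, n_sess * n_seg),
                "session": np.tile(np.repeat(list(config.sessions), n_seg), n_sub),
                "tract": tract,
                "segment": np.tile(np.arange(1, n_seg + 1), n_sub * n_sess),
                "metric": metric,
                "value": vals.reshape(-1),
            }))
    data = pd.concat(frames, ignore_index=True)
    panel = TractProfilePanel(data, session_order=config.sessions, validate=False)
    if config.effects and not magnitudes.any():
        # first effect exists but magnitudes stayed zero (magnitude 0 config)
        eff = config.effects[0]
        magnitudes = eff.group_magnitude + eff.subject_sd * latent
    return panel, magnitudes


def _coupled_exponents(config: CohortConfig, magnitudes: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Learning exponents b_i > 0 with target Spearman(b_i, m_i).

    Gaussian copula: normal scores of the magnitude ranks are mixed with
    independent noise at the latent Pearson correlation 2*sin(pi*rho_s/6)
    that induces the requested Spearman rho, then pushed through a
    lognormal quantile transform (monotone, hence rank-preserving).
    """
    n = len(magnitudes)
    rho_s = config.behavior_coupling_rho
    rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
    ranks = stats.rankdata(magnitudes, method="average")
    z_m = stats.norm.ppf((ranks - 0.375) / (n + 0.25))     # Blom scores
    if np.allclose(z_m, 0):
        z_m = np.zeros(n)
    latent = rho_p * z_m + np.sqrt(max(0.0, 1 - rho_p ** 2)) * rng.standard_normal(n)
    b = np.exp(np.log(config.behavior_b_median) + config.behavior_b_logsd * latent)
    if n >= 4 and np.ptp(magnitudes) > 0 and abs(rho_s) > 0:
        achieved = stats.spearmanr(b, magnitudes).statistic
        if abs(achieved - rho_s) > 0.35:
            warnings.warn(
                f"behavior coupling target rho={rho_s:.2f} not reached "
                f"(achieved {achieved:.2f})", stacklevel=2)
            logger.warning("achieved coupling rho %.3f (target %.3f)",
                           achieved, rho_s)
    return b


def generate_behavior(config: CohortConfig, magnitudes: np.ndarray,
                      rng: np.random.Generator | None = None
                      ) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-trial balance times for 8 training sessions x 15 trials.

    Trial time = ``a_i * session**b_i`` plus Gaussian noise, truncated to
    the [0, 30] s trial duration.  Returns the long-format table and the
    subject exponents ``b_i``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(magnitudes)
    subjects = [f"S{i + 1:02d}" for i in range(n)]
    b = _coupled_exponents(config, magnitudes, rng)
    a = np.clip(config.behavior_a_mean
                + config.behavior_a_sd * rng.standard_normal(n), 0.5, None)
    sess = np.arange(1, config.n_training_sessions + 1)
    mean = a[:, None] * sess[None, :] ** b[:, None]          # (n, sessions)
    noise = config.behavior_noise_sd * rng.standard_normal(
        (n, config.n_training_sessions, config.n_trials))
    times = np.clip(mean[:, :, None] + noise, 0.0, config.trial_cap_s)
    df = pd.DataFrame({
        "subject_id": np.repeat(subjects, config.n_training_sessions * config.n_trials),
        "session": np.tile(np.repeat(sess, config.n_trials), n),
        "trial": np.tile(np.arange(1, config.n_trials + 1),
                         n * config.n_training_sessions),
        "balance_time_s": times.reshape(-1),
    })
    return df, b


def generate_cortical_response(config: CohortConfig, magnitudes: np.ndarray,
                               rng: np.random.Generator | None = None
                               ) -> pd.DataFrame:
    """Cortical ODI change score: ``gamma * m_i + Normal(0, noise_sd)``."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n = len(magnitudes)
    eps = (config.cortical_noise_sd * rng.standard_normal(n)
           if config.cortical_noise_sd > 0 else np.zeros(n))
    return pd.DataFrame({
        "subject_id": [f"S{i + 1:02d}" for i in range(n)],
        "odi_change": config.cortical_gamma * magnitudes + eps,
    })


def simulate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate all three tables of a cohort from one master seed."""
    if config is None:
        config = CohortConfig()
    ss = np.random.SeedSequence(config.seed)
    kids = ss.spawn(3)
    child_seeds = {name: int(k.generate_state(1)[0] % (2 ** 31))
                   for name, k in zip(("profiles", "behavior", "cortical"), kids)}
    logger.info("child seeds: %s", child_seeds)
    panel, magnitudes = generate_tract_profiles(
        config, np.random.default_rng(kids[0]))
    behavior, exponents = generate_behavior(
        config, magnitudes, np.random.default_rng(kids[1]))
    cortical = generate_cortical_response(
        config, magnitudes, np.random.default_rng(kids[2]))
    return SyntheticCohort(panel=panel, behavior=behavior, cortical=cortical,
                           magnitudes=magnitudes, exponents=exponents,
                           child_seeds=child_seeds)
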
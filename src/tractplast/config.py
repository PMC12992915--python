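"""Cohort configuration for the synthetic tract-profile generator.

The synthetic cohort emulates a longitudinal balance-training study:
24 subjects scanned at three sessions four weeks apart (MRI1, MRI2, MRI3),
with a no-intervention control interval (MRI1-MRI2) followed by a motor
learning interval (MRI2-MRI3).  Microstructural metrics are sampled along
29 tractography-defined bundles divided into 98 equidistant segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .exceptions import ConfigurationError

#: The 29 bundles of the motor network analysed in the study design we
#: emulate (TractSeg naming): middle cerebellar peduncle, bilateral inferior
#: and superior cerebellar peduncles, frontopontine and corticospinal
#: tracts, anterior/superior thalamic radiations, thalamo-premotor tracts,
#: striato-fronto-orbital and striato-premotor tracts, SLF I-III, and four
#: anterior corpus callosum subdivisions.
DEFAULT_TRACTS: tuple[str, ...] = (
    "MCP",
    "ICP_left", "ICP_right",
    "SCP_left", "SCP_right",
    "FPT_left", "FPT_right",
    "CST_left", "CST_right",
    "ATR_left", "ATR_right",
    "STR_left", "STR_right",
    "T_PREM_left", "T_PREM_right",
    "ST_FO_left", "ST_FO_right",
    "ST_PREM_left", "ST_PREM_right",
    "SLF_I_left", "SLF_I_right",
    "SLF_II_left", "SLF_II_right",
    "SLF_III_left", "SLF_III_right",
    "CC_1", "CC_2", "CC_3", "CC_4",
)

#: Metric panel: three NODDI volume-fraction/dispersion parameters, four
#: multi-parameter-mapping contrasts, and the aggregate g-ratio.
DEFAULT_METRICS: tuple[str, ...] = (
    "FISO", "FICVF", "ODI", "MT", "R1", "R2star", "PD", "GRATIO",
)

#: Plausible native-unit means and between-voxel scales for healthy adult
#: white matter; the generator works in z-units internally and maps to
#: native units through these, so downstream standardization recovers the
#: injected effect sizes.
METRIC_BASELINES: dict[str, tuple[float, float]] = {
    "FISO": (0.10, 0.02),
    "FICVF": (0.60, 0.05),
    "ODI": (0.25, 0.03),
    "MT": (3.5, 0.30),
    "R1": (1.0, 0.08),
    "R2star": (20.0, 2.0),
    "PD": (70.0, 3.0),
    "GRATIO": (0.70, 0.03),
}

DEFAULT_SESSIONS: tuple[str, ...] = ("MRI1", "MRI2", "MRI3")


@dataclass
class EffectTemplate:
    """A localized multivariate training effect injected into the cohort.

    The effect applies a signed loading pattern over metrics at a set of
    segments of one tract.  ``group_magnitude`` is the mean latent effect at
    MRI3 (z-units); ``control_magnitude`` (default 0) is the mean effect at
    MRI2 and must be zero to reproduce a stable control interval.  Subject
    magnitudes are ``m_i = group_magnitude + subject_sd * d_i`` with a
    standard-normal latent ``d_i`` shared across all templates of a cohort,
    so distributed effects are coherent within subject.
    """

    tract: str
    segments: tuple[int, ...]
    loading_pattern: dict[str, float]
    group_magnitude: float = 1.0
    control_magnitude: float = 0.0
    subject_sd: float = 0.0

    def __post_init__(self) -> None:
        self.segments = tuple(int(s) for s in self.segments)
        norm = math.sqrt(sum(w * w for w in self.loading_pattern.values()))
        if norm == 0:
            raise ConfigurationError("loading_pattern must be non-zero")
        # normalize to unit Euclidean norm
        self.loading_pattern = {m: w / norm for m, w in self.loading_pattern.items()}
        if self.subject_sd < 0:
            raise ConfigurationError("subject_sd must be >= 0")


def default_effects() -> list[EffectTemplate]:
    """Training effects emulating the five tract sections of the study design.

    Right ATR (segments 65-67): free-water-driven decrease; right T_PREM
    (73-74), right FPT (50) and right CST (53): g-ratio-led decreases with
    myelin-metric contributions; left CST (88-89): R2*/PD-led increase.
    """
    return [
        EffectTemplate("ATR_right", (65, 66, 67),
                       {"FISO": -0.9, "FICVF": -0.3, "ODI": -0.1},
                       group_magnitude=1.0, subject_sd=0.4),
        EffectTemplate("T_PREM_right", (73, 74),
                       {"GRATIO": -0.8, "MT": 0.4, "R1": 0.3, "FICVF": 0.2},
                       group_magnitude=1.0, subject_sd=0.4),
        EffectTemplate("FPT_right", (50,),
                       {"GRATIO": -0.8, "MT": 0.4, "FISO": -0.3},
                       group_magnitude=1.0, subject_sd=0.4),
        EffectTemplate("CST_right", (53,),
                       {"GRATIO": -0.8, "R1": 0.4, "MT": 0.3},
                       group_magnitude=1.0, subject_sd=0.4),
        EffectTemplate("CST_left", (88, 89),
                       {"R2star": 0.7, "PD": 0.6, "ODI": 0.2},
                       group_magnitude=1.0, subject_sd=0.4),
    ]


@dataclass
class CohortConfig:
    """Study-design parameters for the synthetic cohort generator.

    SDs are in z-units of the latent metric scale; ``ar_phi`` is the AR(1)
    coefficient of the residual field along segments; ``behavior_coupling_rho``
    is the target Spearman correlation between per-subject effect magnitudes
    and power-law learning exponents; ``cortical_gamma`` is the slope linking
    the latent white-matter magnitude to the cortical ODI change score.
    """

    n_subjects: int = 24
    sessions: tuple[str, ...] = DEFAULT_SESSIONS
    tracts: tuple[str, ...] = DEFAULT_TRACTS
    n_segments: int = 98
    metrics: tuple[str, ...] = DEFAULT_METRICS
    sigma_subject: float = 0.5
    sigma_resid: float = 0.5
    ar_phi: float = 0.7
    effects: list[EffectTemplate] = field(default_factory=default_effects)
    behavior_coupling_rho: float = 0.5
    cortical_gamma: float = -1.0
    cortical_noise_sd: float = 0.3
    # behavioral population: trial time = a_i * session^b_i + noise, capped
    # at the 30 s trial duration; log b_i ~ N(log 0.3, 0.35^2) puts the
    # group exponent near 0.3 with CV ~0.36, matching robust group learning
    behavior_a_mean: float = 10.0
    behavior_a_sd: float = 2.0
    behavior_b_median: float = 0.3
    behavior_b_logsd: float = 0.35
    behavior_noise_sd: float = 2.0
    n_training_sessions: int = 8
    n_trials: int = 15
    trial_cap_s: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.sessions = tuple(self.sessions)
        self.tracts = tuple(self.tracts)
        self.metrics = tuple(self.metrics)
        if self.n_segments < 2:
            raise ConfigurationError("n_segments must be >= 2")
        if not 0.0 <= self.ar_phi < 1.0:
            raise ConfigurationError("ar_phi must lie in [0, 1)")
        if abs(self.behavior_coupling_rho) > 1.0:
            raise ConfigurationError("|behavior_coupling_rho| must be <= 1")
        for name, value in (
            ("sigma_subject", self.sigma_subject),
            ("sigma_resid", self.sigma_resid),
            ("cortical_noise_sd", self.cortical_noise_sd),
            ("behavior_noise_sd", self.behavior_noise_sd),
        ):
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if len(set(self.metrics)) != len(self.metrics):
            raise ConfigurationError("metric names must be unique")
        if len(set(self.tracts)) != len(self.tracts):
            raise ConfigurationError("tract names must be unique")
        for eff in self.effects:
            if eff.tract not in self.tracts:
                raise ConfigurationError(
                    f"effect references unknown tract {eff.tract!r}")
            unknown = set(eff.loading_pattern) - set(self.metrics)
            if unknown:
                raise ConfigurationError(
                    f"effect references unknown metrics {sorted(unknown)}")
            bad = [s for s in eff.segments if not 1 <= s <= self.n_segments]
            if bad:
                raise ConfigurationError(
                    f"effect segments out of range: {bad}")
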
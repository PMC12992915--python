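"""Power-law learning curves for the dynamic balancing task.

Motor learning is quantified per subject by fitting a general power
function ``mean_s = a * s**b`` to within-session mean balance times over
the eight training sessions; the exponent b is the learning rate.  The
group-level test asks whether exponents exceed zero (one-sample t test,
one-sided by default, with the two-sided p also reported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = ["LearningCurveFit", "PowerLawModel", "fit_power_law",
           "fit_learning_curves", "group_exponent_test", "GroupExponentTest"]


@dataclass
class LearningCurveFit:
    """Per-subject power-law fit ``y = a * s**b`` (+ offset c if 3-parameter)."""

    a: float
    b: float
    c: float
    resid_sd: float
    converged: bool
    n_sessions: int

    def predict(self, sessions) -> np.ndarray:
        s = np.asarray(sessions, dtype=float)
        return self.c + self.a * s ** self.b


class PowerLawModel:
    """Nonlinear least-squares power-law model of session-mean performance.

    Parameters
    ----------
    sessions, means
        Training-session indices (1-based) and within-session mean balance
        times.  Alternatively build from per-trial records with
        :meth:`from_trials`.
    offset
        If True fit the 3-parameter form ``y = c + a * s**b``.
    """

    def __init__(self, sessions, means, offset: bool = False):
        self.sessions = np.asarray(sessions, dtype=float)
        self.means = np.asarray(means, dtype=float)
        if len(self.sessions) < 3:
            raise ValueError("need >= 3 sessions to fit a power law")
        if np.any(self.sessions <= 0):
            raise ValueError("session indices must be positive (1-based)")
        self.offset = offset

    @classmethod
    def from_trials(cls, records: pd.DataFrame, offset: bool = False
                    ) -> "PowerLawModel":
        """Build from a per-trial table with columns session, balance_time_s."""
        means = records.groupby("session")["balance_time_s"].mean()
        return cls(means.index.to_numpy(), means.to_numpy(), offset=offset)

    def _initial(self) -> tuple[float, float]:
        # log-log linear regression; exact on noise-free power-law data
        y = np.clip(self.means, 1e-9, None)
        slope, intercept = np.polyfit(np.log(self.sessions), np.log(y), 1)
        return float(np.exp(intercept)), float(slope)

    def fit(self) -> LearningCurveFit:
        a0, b0 = self._initial()
        starts = [(a0, b0), (max(self.means.mean(), 1e-6), 0.0),
                  (max(self.means[0], 1e-6), 0.3)]
        best, best_sse = None, np.inf
        for a_s, b_s in starts:
            try:
                if self.offset:
                    p, _ = optimize.curve_fit(
                        lambda s, a, b, c: c + a * s ** b,
                        self.sessions, self.means, p0=(a_s, b_s, 0.0),
                        maxfev=20000)
                    a, b, c = p
                else:
                    p, _ = optimize.curve_fit(
                        lambda s, a, b: a * s ** b,
                        self.sessions, self.means, p0=(a_s, b_s),
                        maxfev=20000)
                    a, b = p
                    c = 0.0
            except RuntimeError:
                continue
            resid = self.means - (c + a * self.sessions ** b)
            sse = float(resid @ resid)
            if sse < best_sse:
                best, best_sse = (float(a), float(b), float(c)), sse
        if best is None:
            logger.warning("power-law fit failed to converge")
            return LearningCurveFit(np.nan, np.nan, 0.0, np.nan, False,
                                    len(self.sessions))
        a, b, c = best
        dof = max(len(self.sessions) - (3 if self.offset else 2), 1)
        return LearningCurveFit(a, b, c, float(np.sqrt(best_sse / dof)), True,
                                len(self.sessions))


def fit_power_law(records: pd.DataFrame, offset: bool = False) -> LearningCurveFit:
    """Fit one subject's trials (columns session, balance_time_s)."""
    return PowerLawModel.from_trials(records, offset=offset).fit()


def fit_learning_curves(behavior: pd.DataFrame, offset: bool = False
                        ) -> pd.DataFrame:
    """Fit every subject in a long-format behavior table.

    Returns a frame indexed by subject_id with columns a, b, c, resid_sd,
    converged.
    """
    rows = {}
    for sid, sub in behavior.groupby("subject_id"):
        fit = fit_power_law(sub, offset=offset)
        rows[sid] = {"a": fit.a, "b": fit.b, "c": fit.c,
                     "resid_sd": fit.resid_sd, "converged": fit.converged}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("subject_id")


@dataclass
class GroupExponentTest:
    t: float
    df: int
    p_one_sided: float
    p_two_sided: float
    mean_b: float
    n: int


def group_exponent_test(exponents) -> GroupExponentTest:
    """One-sample t test of learning exponents against zero.

    One-sided (greater) by convention — learning implies b > 0 — with the
    two-sided p reported alongside.  Zero variance yields NaN statistics.
    """
    b = np.asarray(exponents, dtype=float)
    b = b[np.isfinite(b)]
    n = len(b)
    if n < 2:
        raise ValueError("need >= 2 converged exponents")
    if np.ptp(b) == 0:
        logger.warning("zero variance of exponents: test undefined")
        return GroupExponentTest(np.nan, n - 1, np.nan, np.nan,
                                 float(b.mean()), n)
    res = stats.ttest_1samp(b, 0.0, alternative="greater")
    res2 = stats.ttest_1samp(b, 0.0)
    return GroupExponentTest(float(res.statistic), n - 1, float(res.pvalue),
                             float(res2.pvalue), float(b.mean()), n)
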
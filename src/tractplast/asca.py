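"""Per-segment multivariate longitudinal modelling (repeated-measures ASCA).

For one tract segment, each microstructural metric is z-scored over all
(subject, session) observations and modelled by a linear mixed model

    outcome ~ time + (1 | subject)

with the baseline session as reference and a random subject intercept.
The per-metric fixed time effects are assembled into an observation-by-
metric effect matrix, which is decomposed by an uncentered SVD (reference
coding anchors the baseline at the origin), yielding session-level
principal-component scores and metric loadings.  Uncertainty comes from a
cluster bootstrap over subjects (the full standardize -> LMM -> PCA
pipeline rerun per replicate) with BCa intervals; a segment is flagged
"plastic" when the PC1 score interval at the post-training session
overlaps neither pre-training interval while the two pre-training
intervals overlap each other (stable control interval).

For balanced complete panels the GLS fixed-effect estimate of a
random-intercept model equals the session-mean differences exactly, so
the bootstrap uses that closed form; unbalanced panels fall back to
REML fits via :class:`statsmodels.regression.mixed_linear_model.MixedLM`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._bca import bca_interval
from .exceptions import ConvergenceError
from .panel import TractProfilePanel

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentASCA", "SegmentASCAResults",
    "standardize_panel", "fit_segment_lmm", "build_time_effect_matrix",
    "decompose_effects", "classify_segment",
]


# --------------------------------------------------------------- primitives

def standardize_panel(panel: TractProfilePanel, tract: str, segment: int,
                      metrics=None):
    """Z-score each metric of one segment over all observations.

    Returns ``(z, subjects, sessions, metrics, means, sds)`` where ``z`` is a
    (subjects x sessions x metrics) array.  Zero-variance metrics are
    excluded with a warning.  Means/SDs (ddof=1) are retained so subject
    scores can be predicted on the same scale and observations can be
    de-standardized exactly.
    """
    arr, subjects, sessions, mets = panel.segment_array(tract, segment, metrics)
    return _standardize_array(arr, subjects, sessions, mets)


def _standardize_array(arr, subjects, sessions, mets):
    flat = arr.reshape(-1, arr.shape[2])
    means = np.nanmean(flat, axis=0)
    sds = np.nanstd(flat, axis=0, ddof=1)
    keep = sds > 0
    if not keep.all():
        dropped = [m for m, k in zip(mets, keep) if not k]
        warnings.warn(f"excluding zero-variance metrics: {dropped}", stacklevel=2)
        arr = arr[:, :, keep]
        mets = [m for m, k in zip(mets, keep) if k]
        means, sds = means[keep], sds[keep]
    z = (arr - means) / sds
    return z, subjects, sessions, mets, means, sds


def fit_segment_lmm(observations: pd.DataFrame, metric: str,
                    session_order=("MRI1", "MRI2", "MRI3")):
    """REML mixed-model fit of one metric: outcome ~ time + (1 | subject).

    ``observations`` is long-format with columns subject_id, session,
    metric, value (standardized or raw).  Returns ``(beta, var_subject,
    var_resid, singular)`` with ``beta`` a Series of session effects
    relative to baseline.  A singular fit (subject variance at the zero
    boundary) is flagged, not raised.
    """
    import statsmodels.formula.api as smf

    df = observations[observations["metric"] == metric].copy()
    sessions = [s for s in session_order if s in set(df["session"])]
    if df["subject_id"].nunique() < 2 or len(sessions) < 2:
        raise ValueError("need >= 2 subjects and >= 2 sessions")
    df["session"] = pd.Categorical(df["session"], categories=sessions, ordered=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value ~ C(session)", df, groups=df["subject_id"])
        res = model.fit(reml=True)
    beta = pd.Series(
        {s: float(res.fe_params.get(f"C(session)[T.{s}]", 0.0)) for s in sessions[1:]})
    var_subject = float(res.cov_re.iloc[0, 0])
    var_resid = float(res.scale)
    singular = var_subject < 1e-10
    return beta, var_subject, var_resid, singular


def build_time_effect_matrix(betas: pd.DataFrame,
                             session_of_row) -> np.ndarray:
    """Observation-level effect matrix from per-metric fixed effects.

    ``betas`` is (sessions x metrics) with an all-zero baseline row;
    ``session_of_row`` gives each observation's session label.  Each row of
    the result is the fixed time-effect vector of that observation's
    session; baseline rows are zero under reference coding.
    """
    return betas.loc[list(session_of_row)].to_numpy()


def decompose_effects(effect_matrix: np.ndarray, row_weights=None):
    """Uncentered SVD of the (unique-row) effect matrix.

    ``effect_matrix`` holds one row per session (or per observation);
    ``row_weights`` optionally weight rows by observation counts when unique
    session rows are passed.  Returns ``(scores, loadings, explained)``:
    session-row projections, unit-norm metric loadings (sign fixed so the
    largest-|loading| metric of each component is positive), and explained
    variance fractions.  An all-zero matrix yields zero components.
    """
    M = np.asarray(effect_matrix, dtype=float)
    W = np.ones(M.shape[0]) if row_weights is None else np.asarray(row_weights, float)
    weighted = M * np.sqrt(W)[:, None]
    if not np.any(weighted):
        k = min(M.shape)
        return np.zeros((M.shape[0], k)), np.zeros((M.shape[1], k)), np.zeros(k)
    U, S, Vt = np.linalg.svd(weighted, full_matrices=False)
    nz = S > S[0] * 1e-12
    S, Vt = S[nz], Vt[nz]
    loadings = Vt.T                                   # (metrics, comps)
    # sign convention: largest-|loading| metric positive per component
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
    scores = M @ loadings                             # session-row projections
    explained = S ** 2 / np.sum(S ** 2)
    return scores, loadings, explained


def _overlap(ci_a, ci_b) -> bool:
    return ci_a[0] <= ci_b[1] and ci_b[0] <= ci_a[1]


def classify_segment(score_cis: dict) -> dict:
    """Significance flags from PC1 score intervals at the three sessions.

    ``score_cis`` maps session label -> (low, high), ordered baseline,
    control-end, post-training.  stable_control: the two pre-training
    intervals overlap; change_13 / change_23: the post-training interval is
    disjoint from the baseline / control-end interval; plastic: all three.
    """
    sessions = list(score_cis)
    if len(sessions) != 3:
        raise ValueError("classification requires exactly 3 sessions")
    c1, c2, c3 = (score_cis[s] for s in sessions)
    stable = _overlap(c1, c2)
    ch13 = not _overlap(c3, c1)
    ch23 = not _overlap(c3, c2)
    return {"stable_control": stable, "change_13": ch13, "change_23": ch23,
            "plastic": stable and ch13 and ch23}


# ----------------------------------------------------------------- the model

def _fit_balanced(z: np.ndarray):
    """Closed-form session effects + SVD for a standardized balanced array."""
    n = z.shape[0]
    sm = z.mean(axis=0)                       # (sessions, metrics)
    R = sm - sm[0]                            # baseline-referenced unique rows
    weights = np.full(z.shape[1], n)
    scores, loadings, explained = decompose_effects(R, row_weights=weights)
    return R, scores, loadings, explained


def _fit_unbalanced(arr, subjects, sessions, mets):
    """MixedLM path: per-metric REML fits on the standardized long data."""
    z, subjects, sessions, mets, means, sds = _standardize_array(
        arr, subjects, sessions, mets)
    rows = []
    for i, sid in enumerate(subjects):
        for j, sess in enumerate(sessions):
            for k, met in enumerate(mets):
                v = z[i, j, k]
                if np.isfinite(v):
                    rows.append((sid, sess, met, v))
    df = pd.DataFrame(rows, columns=["subject_id", "session", "metric", "value"])
    betas = pd.DataFrame(0.0, index=list(sessions), columns=list(mets))
    for met in mets:
        beta, *_ = fit_segment_lmm(df, met, session_order=sessions)
        for s, b in beta.items():
            betas.loc[s, met] = b
    counts = df.groupby("session")["value"].size().reindex(list(sessions)).to_numpy()
    R = betas.to_numpy()
    scores, loadings, explained = decompose_effects(
        R, row_weights=counts / len(mets))
    return z, mets, means, sds, R, scores, loadings, explained


@dataclass
class SegmentASCAResults:
    """Fitted per-segment model: effects, decomposition, intervals, flags."""

    tract: str
    segment: int
    subjects: list
    sessions: list
    metrics: list
    means: np.ndarray
    sds: np.ndarray
    beta: pd.DataFrame                 # sessions x metrics, baseline row zero
    scores: pd.DataFrame               # sessions x components
    loadings: pd.DataFrame             # metrics x components
    explained_variance: np.ndarray
    score_cis: pd.DataFrame | None = None      # sessions x [low, high] (PC1)
    loading_cis: pd.DataFrame | None = None    # metrics x [low, high] (PC1)
    flags: dict = field(default_factory=dict)
    B: int = 0
    seed: int | None = None
    n_boot_failed: int = 0
    _z: np.ndarray | None = None

    @property
    def plastic(self) -> bool:
        return bool(self.flags.get("plastic", False))

    def predict_scores(self) -> pd.DataFrame:
        """Per-subject per-session PC1 scores.

        Each subject's standardized metric vector is projected onto the PC1
        loadings; missing metrics make the score missing (logged).
        """
        pc1 = self.loadings.iloc[:, 0].to_numpy()
        out = np.einsum("ijk,k->ij", self._z, pc1)
        missing = ~np.isfinite(self._z).all(axis=2)
        if missing.any():
            logger.warning("%d subject-sessions with missing metrics: "
                           "scores set to NaN", int(missing.sum()))
            out[missing] = np.nan
        return pd.DataFrame(out, index=self.subjects, columns=self.sessions)

    def to_json(self) -> str:
        """Serialize estimates, intervals, flags and provenance (B, seed)."""
        import json

        payload = {
            "tract": self.tract, "segment": self.segment,
            "sessions": list(self.sessions), "metrics": list(self.metrics),
            "beta": self.beta.to_dict(),
            "scores": self.scores.to_dict(),
            "loadings": self.loadings.to_dict(),
            "explained_variance": list(map(float, self.explained_variance)),
            "score_cis": None if self.score_cis is None
            else self.score_cis.to_dict(),
            "loading_cis": None if self.loading_cis is None
            else self.loading_cis.to_dict(),
            "flags": self.flags,
            "provenance": {"B": self.B, "seed": self.seed,
                           "n_boot_failed": self.n_boot_failed,
                           "n_subjects": len(self.subjects)},
        }
        return json.dumps(payload, indent=2)

    def summary(self) -> str:
        lines = [
            f"Segment ASCA: tract={self.tract} segment={self.segment}",
            f"  subjects={len(self.subjects)}  sessions={list(self.sessions)}  "
            f"metrics={len(self.metrics)}",
            f"  PC1 explained variance: {self.explained_variance[0]:.1%}"
            if len(self.explained_variance) else "  (zero effect matrix)",
        ]
        if self.score_cis is not None:
            lines.append("  PC1 session scores (95% BCa CI):")
            for s in self.sessions:
                sc = self.scores.loc[s].iloc[0]
                lo, hi = self.score_cis.loc[s]
                lines.append(f"    {s}: {sc:+.3f}  [{lo:+.3f}, {hi:+.3f}]")
            lines.append("  PC1 loadings (95% BCa CI):")
            for m in self.metrics:
                ld = self.loadings.loc[m].iloc[0]
                lo, hi = self.loading_cis.loc[m]
                lines.append(f"    {m}: {ld:+.3f}  [{lo:+.3f}, {hi:+.3f}]")
            lines.append(f"  flags: {self.flags}  (B={self.B}, "
                         f"failed={self.n_boot_failed})")
        return "\n".join(lines)


class SegmentASCA:
    """Multivariate longitudinal model of one tract segment.

    Parameters
    ----------
    panel
        A :class:`TractProfilePanel`.
    tract, segment
        The segment to model.
    metrics
        Metric subset (default: all metrics present at the segment).
    """

    def __init__(self, panel: TractProfilePanel, tract: str, segment: int,
                 metrics=None):
        self.tract, self.segment = tract, int(segment)
        arr, subjects, sessions, mets = panel.segment_array(tract, segment, metrics)
        if len(sessions) < 2:
            raise ValueError("need >= 2 sessions")
        if len(subjects) < 2:
            raise ValueError("need >= 2 subjects")
        self.arr, self.subjects, self.sessions, self.mets = arr, subjects, sessions, mets
        self.balanced = bool(np.isfinite(arr).all())

    # internal: fit a balanced raw array, return everything or None on failure
    def _point_fit(self, arr):
        flat = arr.reshape(-1, arr.shape[2])
        means = flat.mean(axis=0)
        sds = flat.std(axis=0, ddof=1)
        if np.any(sds == 0):
            return None
        z = (arr - means) / sds
        R, scores, loadings, explained = _fit_balanced(z)
        return z, means, sds, R, scores, loadings, explained

    def fit(self, B: int = 1000, seed: int | None = None,
            alpha: float = 0.05, max_fail_frac: float = 0.10
            ) -> SegmentASCAResults:
        """Fit the model; ``B`` bootstrap replicates give BCa intervals.

        ``B = 0`` skips the bootstrap (point estimates only).
        """
        n = len(self.subjects)
        if self.balanced:
            fitted = self._point_fit(self.arr)
            if fitted is None:
                # zero-variance metric: exclude and refit on the remainder
                flat = self.arr.reshape(-1, self.arr.shape[2])
                keep = flat.std(axis=0, ddof=1) > 0
                dropped = [m for m, k in zip(self.mets, keep) if not k]
                warnings.warn(f"excluding zero-variance metrics: {dropped}",
                              stacklevel=2)
                self.arr = self.arr[:, :, keep]
                self.mets = [m for m, k in zip(self.mets, keep) if k]
                if len(self.mets) == 0:
                    raise ValueError("all metrics have zero variance")
                fitted = self._point_fit(self.arr)
            z, means, sds, R, scores, loadings, explained = fitted
            mets = list(self.mets)
        else:
            z, mets, means, sds, R, scores, loadings, explained = _fit_unbalanced(
                self.arr, self.subjects, self.sessions, self.mets)
        ncomp = loadings.shape[1]
        comp_names = [f"PC{k + 1}" for k in range(ncomp)]
        res = SegmentASCAResults(
            tract=self.tract, segment=self.segment,
            subjects=list(self.subjects), sessions=list(self.sessions),
            metrics=list(mets), means=means, sds=sds,
            beta=pd.DataFrame(R, index=list(self.sessions), columns=list(mets)),
            scores=pd.DataFrame(scores, index=list(self.sessions),
                                columns=comp_names),
            loadings=pd.DataFrame(loadings, index=list(mets), columns=comp_names),
            explained_variance=explained, seed=seed, _z=z)
        if B <= 0 or ncomp == 0:
            return res
        if n < 5:
            raise ValueError("cluster bootstrap needs >= 5 subjects")
        if not self.balanced:
            logger.warning("unbalanced panel: bootstrap refits MixedLM per "
                           "replicate; consider reducing B")

        pc1_load = loadings[:, 0]
        rng = np.random.default_rng(seed)
        boot_scores = np.full((B, len(self.sessions)), np.nan)
        boot_loads = np.full((B, len(mets)), np.nan)
        failed = 0
        for b in range(B):
            idx = rng.integers(0, n, size=n)
            rep = self._replicate_fit(idx, mets)
            if rep is None:
                failed += 1
                continue
            r_scores, r_loads = rep
            sign = 1.0 if r_loads @ pc1_load >= 0 else -1.0
            boot_scores[b] = sign * r_scores
            boot_loads[b] = sign * r_loads
        if failed > max_fail_frac * B:
            raise ConvergenceError(
                f"{failed}/{B} bootstrap replicates failed")
        if failed:
            logger.warning("%d/%d bootstrap replicates dropped", failed, B)
        # jackknife over subjects for BCa acceleration
        jack_scores = np.full((n, len(self.sessions)), np.nan)
        jack_loads = np.full((n, len(mets)), np.nan)
        for i in range(n):
            idx = np.array([j for j in range(n) if j != i])
            rep = self._replicate_fit(idx, mets)
            if rep is None:
                continue
            r_scores, r_loads = rep
            sign = 1.0 if r_loads @ pc1_load >= 0 else -1.0
            jack_scores[i] = sign * r_scores
            jack_loads[i] = sign * r_loads

        score_cis = pd.DataFrame(
            [bca_interval(scores[j, 0], boot_scores[:, j], jack_scores[:, j],
                          alpha=alpha) for j in range(len(self.sessions))],
            index=list(self.sessions), columns=["low", "high"])
        loading_cis = pd.DataFrame(
            [bca_interval(pc1_load[k], boot_loads[:, k], jack_loads[:, k],
                          alpha=alpha) for k in range(len(mets))],
            index=list(mets), columns=["low", "high"])
        res.score_cis, res.loading_cis = score_cis, loading_cis
        res.B, res.n_boot_failed = B, failed
        if len(self.sessions) == 3:
            res.flags = classify_segment(
                {s: tuple(score_cis.loc[s]) for s in self.sessions})
        return res

    def _replicate_fit(self, idx, mets):
        """Refit the full pipeline on a subject resample; PC1 only."""
        arr = self.arr[idx]
        if self.balanced:
            fitted = self._point_fit(arr)
            if fitted is None:
                return None
            *_, scores, loadings, explained = fitted
            if loadings.shape[1] == 0:
                return None
            return scores[:, 0], loadings[:, 0]
        try:
            subjects = [f"B{j}" for j in range(len(idx))]
            out = _fit_unbalanced(arr, subjects, self.sessions, mets)
            scores, loadings = out[5], out[6]
            if loadings.shape[1] == 0:
                return None
            return scores[:, 0], loadings[:, 0]
        except Exception:
            return None
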
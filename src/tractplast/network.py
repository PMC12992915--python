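"""Network-level stage: covariance structure of distributed plasticity.

The per-tract-section latent change scores (PC1 interval changes per
subject) form a subjects-by-sections matrix.  This module asks whether the
distributed changes share a single dimension — PCA on the correlation
matrix with unrotated axes, Horn parallel analysis for component
retention, and factorability diagnostics (KMO sampling adequacy from
anti-image partial correlations, Bartlett's sphericity test, determinant
check) — and whether that shared dimension predicts independently measured
cortical microstructural change (robust MM regression with LOOCV).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .robust import LoocvReport, MMRegression, MMRegressionResults, loocv

logger = logging.getLogger(__name__)

__all__ = [
    "pca_change_scores", "parallel_analysis", "factorability",
    "FactorabilityReport", "PcaReport", "LatentNetworkModel",
    "LatentNetworkResults",
]


def _clean_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    df = matrix.dropna(axis=0, how="any")
    const = [c for c in df.columns if df[c].nunique() <= 1]
    if const:
        warnings.warn(f"excluding constant columns: {const}", stacklevel=3)
        df = df.drop(columns=const)
    return df


@dataclass
class PcaReport:
    loadings: pd.DataFrame             # variables x components
    explained_variance: np.ndarray     # fraction per component
    scores: pd.DataFrame               # subjects x components
    eigenvalues: np.ndarray


def pca_change_scores(matrix: pd.DataFrame) -> PcaReport:
    """Unrotated PCA of the latent change matrix, on the correlation matrix.

    Component signs are fixed so the mean loading is positive; subject
    scores are the projections of the standardized data.  Constant columns
    are excluded with a warning; only complete rows enter.
    """
    df = _clean_matrix(matrix)
    if df.shape[0] < 3 or df.shape[1] < 2:
        raise ValueError("need >= 3 complete rows and >= 2 variables")
    Z = (df - df.mean()) / df.std(ddof=1)
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    # loadings scaled by sqrt(eigenvalue); sign: mean loading positive
    load = eigvec * np.sqrt(eigval)
    for k in range(load.shape[1]):
        if load[:, k].mean() < 0:
            load[:, k] *= -1.0
            eigvec[:, k] *= -1.0
    comp = [f"PC{k + 1}" for k in range(load.shape[1])]
    scores = Z.to_numpy() @ eigvec
    return PcaReport(
        loadings=pd.DataFrame(load, index=df.columns, columns=comp),
        explained_variance=eigval / eigval.sum(),
        scores=pd.DataFrame(scores, index=df.index, columns=comp),
        eigenvalues=eigval)


def parallel_analysis(matrix: pd.DataFrame, n_sim: int = 1000,
                      criterion: str = "mean",
                      seed: int | None = None) -> int:
    """Horn's parallel analysis on the correlation matrix.

    Retains components whose observed eigenvalue exceeds the ``criterion``
    (mean or the 95th percentile) of eigenvalues from ``n_sim`` simulated
    uncorrelated Gaussian datasets of identical shape.  Scale-invariant by
    construction (correlation-based).
    """
    df = _clean_matrix(matrix)
    n, p = df.shape
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(df.to_numpy(), rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    sim = np.empty((n_sim, p))
    for s in range(n_sim):
        Xs = rng.standard_normal((n, p))
        sim[s] = np.sort(np.linalg.eigvalsh(np.corrcoef(Xs, rowvar=False)))[::-1]
    if criterion == "mean":
        ref = sim.mean(axis=0)
    elif criterion in ("p95", "percentile95"):
        ref = np.percentile(sim, 95, axis=0)
    else:
        raise ValueError("criterion must be 'mean' or 'p95'")
    exceeds = obs > ref
    # retention stops at the first non-exceeding rank
    n_factors = 0
    for e in exceeds:
        if not e:
            break
        n_factors += 1
    return n_factors


@dataclass
class FactorabilityReport:
    kmo_overall: float
    kmo_per_variable: pd.Series
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    determinant: float
    determinant_ok: bool               # exceeds the 1e-5 multicollinearity floor
    n: int
    p: int

    def summary(self) -> str:
        return (f"KMO = {self.kmo_overall:.2f} (per-variable "
                f"{self.kmo_per_variable.min():.2f}-"
                f"{self.kmo_per_variable.max():.2f}); Bartlett chi2"
                f"({self.bartlett_df}) = {self.bartlett_chi2:.2f}, "
                f"p = {self.bartlett_p:.3g}; det(R) = {self.determinant:.3g} "
                f"({'>' if self.determinant_ok else '<='} 1e-05)")


def factorability(matrix: pd.DataFrame) -> FactorabilityReport:
    """KMO, Bartlett sphericity and determinant check for PCA adequacy.

    KMO compares squared marginal correlations against squared anti-image
    partial correlations from the scaled inverse correlation matrix; for
    p = 2 the partial equals the marginal correlation, so the overall KMO
    is exactly 0.5.
    """
    df = _clean_matrix(matrix)
    n, p = df.shape
    if p < 2:
        raise ValueError("need >= 2 variables")
    if n <= p:
        warnings.warn("n <= p: factorability diagnostics unstable", stacklevel=2)
    R = np.corrcoef(df.to_numpy(), rowvar=False)
    det = float(np.linalg.det(R))
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * np.log(max(det, 1e-300))
    dof = p * (p - 1) // 2
    bart_p = float(stats.chi2.sf(chi2, dof))
    # anti-image partial correlations
    try:
        Rinv = np.linalg.inv(R)
        d = np.sqrt(np.diag(Rinv))
        Q = -Rinv / np.outer(d, d)                 # partial correlations
        np.fill_diagonal(Q, 0.0)
        R0 = R.copy()
        np.fill_diagonal(R0, 0.0)
        r2 = R0 ** 2
        q2 = Q ** 2
        kmo_overall = float(r2.sum() / (r2.sum() + q2.sum()))
        kmo_var = r2.sum(axis=0) / (r2.sum(axis=0) + q2.sum(axis=0))
    except np.linalg.LinAlgError:
        logger.warning("singular correlation matrix: KMO undefined")
        kmo_overall = np.nan
        kmo_var = np.full(p, np.nan)
    return FactorabilityReport(
        kmo_overall=kmo_overall,
        kmo_per_variable=pd.Series(kmo_var, index=df.columns),
        bartlett_chi2=float(max(chi2, 0.0)), bartlett_df=dof,
        bartlett_p=bart_p, determinant=det,
        determinant_ok=det > 1e-5, n=n, p=p)


@dataclass
class LatentNetworkResults:
    """Joint report of the network-level analyses."""

    pca: PcaReport
    factorability: FactorabilityReport
    n_factors_parallel: int
    simple_fit: MMRegressionResults          # cortical ~ PC1 score
    multiple_fit: MMRegressionResults        # cortical ~ all sections
    simple_loocv: LoocvReport
    multiple_loocv: LoocvReport
    columns: list = field(default_factory=list)

    def summary(self) -> str:
        ev1 = self.pca.explained_variance[0]
        lines = [
            "Latent white-matter plasticity network",
            f"  sections: {self.columns}",
            f"  PC1 explains {ev1:.1%} of variance; parallel analysis retains "
            f"{self.n_factors_parallel} factor(s)",
            "  " + self.factorability.summary(),
            "  Simple robust regression (cortical change ~ PC1):",
            "  " + self.simple_fit.summary().replace("\n", "\n  "),
            f"  LOOCV: MSE {self.simple_loocv.mse:.2f}, RMSE "
            f"{self.simple_loocv.rmse:.2f}, 1 - SSE_model/SSE_null = "
            f"{self.simple_loocv.sse_ratio:+.2f}",
            "  Multiple robust regression (all sections; omnibus only — "
            "coefficients withheld under multicollinearity):",
            f"    robust R2 = {self.multiple_fit.r_squared:.3f}, pseudo-F"
            f"({self.multiple_fit.df_num}, {self.multiple_fit.df_den}) = "
            f"{self.multiple_fit.pseudo_f:.2f}, p = "
            f"{self.multiple_fit.f_pvalue:.4g}, condition number "
            f"{self.multiple_fit.condition_number:.3g}",
            f"  LOOCV: MSE {self.multiple_loocv.mse:.2f}, RMSE "
            f"{self.multiple_loocv.rmse:.2f}, 1 - SSE_model/SSE_null = "
            f"{self.multiple_loocv.sse_ratio:+.2f}",
        ]
        return "\n".join(lines)


class LatentNetworkModel:
    """Cross-tissue model: cortical change as a function of WM plasticity.

    Parameters
    ----------
    change_matrix
        Subjects x tract-sections matrix of latent (PC1) change scores.
    cortical
        Per-subject cortical change scores (Series aligned by index, or a
        frame with columns subject_id / odi_change).
    """

    def __init__(self, change_matrix: pd.DataFrame,
                 cortical: pd.Series | pd.DataFrame):
        if isinstance(cortical, pd.DataFrame):
            cortical = cortical.set_index("subject_id")["odi_change"]
        df = change_matrix.dropna(axis=0, how="any")
        common = df.index.intersection(cortical.dropna().index)
        if len(common) < 5:
            raise ValueError("need >= 5 complete subjects")
        self.change = df.loc[common]
        self.cortical = cortical.loc[common]

    def fit(self, B_boot: int = 2000, seed: int | None = None,
            n_sim_parallel: int = 1000) -> LatentNetworkResults:
        pca = pca_change_scores(self.change)
        fact = factorability(self.change)
        n_factors = parallel_analysis(self.change, n_sim=n_sim_parallel,
                                      seed=seed)
        y = self.cortical.to_numpy()
        pc1 = pca.scores["PC1"].to_numpy()
        simple = MMRegression(y, pc1, exog_names=["PC1"]).fit(
            B_boot=B_boot, seed=seed)
        multiple = MMRegression(y, self.change.to_numpy(),
                                exog_names=list(self.change.columns)).fit(
            B_boot=0, seed=seed)
        simple_cv = loocv(y, pc1)
        multiple_cv = loocv(y, self.change.to_numpy())
        return LatentNetworkResults(
            pca=pca, factorability=fact, n_factors_parallel=n_factors,
            simple_fit=simple, multiple_fit=multiple,
            simple_loocv=simple_cv, multiple_loocv=multiple_cv,
            columns=list(self.change.columns))
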
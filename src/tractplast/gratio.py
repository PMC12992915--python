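"""Calibrated aggregate g-ratio mapping from MT and NODDI volume fractions.

The aggregate g-ratio is a voxel-level proxy for the ratio of inner (axon)
to outer (axon + myelin) fiber radius.  Magnetization transfer saturation
(MT) serves as a proxy for the myelin volume fraction via a calibration
factor alpha, MVF = alpha * MT; the NODDI intracellular and isotropic
volume fractions give the axonal volume fraction
AVF = (1 - alpha*MT) * (1 - FISO) * FICVF, and

    g = sqrt(1 - MVF / FVF),   FVF = MVF + AVF.

Alpha is calibrated per subject so that g in a splenium reference region
equals an electron-microscopy reference value (default g* = 0.70); the
cohort alpha is the median of the per-subject values.

A ``literal_eq1`` flag additionally exposes the variant
``g = sqrt(1 - MVF/AVF)`` (myelin fraction normalized by the axonal rather
than the total fiber volume), which arises when the denominator omits the
myelin compartment; the standard form above is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import CalibrationError

__all__ = ["compute_g", "calibrate_alpha", "calibrate_cohort",
           "sensitivity_scan", "CalibrationResult"]


def compute_g(mt, ficvf, fiso, alpha: float, literal_eq1: bool = False):
    """Aggregate g-ratio, element-wise over scalars or arrays.

    Invalid inputs (``alpha*MT >= 1``, zero fiber volume, or a negative
    radicand in the literal variant) map to NaN — never silently clamped.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    mt = np.asarray(mt, dtype=float)
    ficvf = np.asarray(ficvf, dtype=float)
    fiso = np.asarray(fiso, dtype=float)
    mvf = alpha * mt
    avf = (1.0 - mvf) * (1.0 - fiso) * ficvf
    with np.errstate(invalid="ignore", divide="ignore"):
        if literal_eq1:
            ratio = np.where(avf > 0, mvf / avf, np.nan)
            g = np.sqrt(np.where(ratio <= 1.0, 1.0 - ratio, np.nan))
        else:
            fvf = mvf + avf
            g = np.sqrt(np.where(fvf > 0, avf / fvf, np.nan))
        g = np.where((mvf < 1.0) & (mvf >= 0.0), g, np.nan)
    return float(g) if g.ndim == 0 else g


def calibrate_alpha(roi_mt: float, roi_ficvf: float, roi_fiso: float,
                    g_star: float = 0.70, literal_eq1: bool = False) -> float:
    """Closed-form alpha such that the reference-region g equals ``g_star``.

    With A0 = (1 - FISO) * FICVF the default form inverts to
    ``alpha*MT = A0*(1 - g*^2) / (A0*(1 - g*^2) + g*^2)``; the literal
    variant to ``alpha*MT = A0*(1 - g*^2) / (1 + A0*(1 - g*^2))``.
    """
    if not 0.0 < g_star <= 1.0:
        raise CalibrationError("g_star must lie in (0, 1]")
    if not np.isfinite([roi_mt, roi_ficvf, roi_fiso]).all():
        raise CalibrationError("ROI means must be finite")
    a0 = (1.0 - roi_fiso) * roi_ficvf
    if a0 <= 0:
        raise CalibrationError("reference region has zero axonal volume (A0 = 0)")
    if roi_mt <= 0:
        raise CalibrationError("reference-region MT must be positive")
    t = a0 * (1.0 - g_star ** 2)
    m = t / (1.0 + t) if literal_eq1 else t / (t + g_star ** 2)
    return m / roi_mt


@dataclass
class CalibrationResult:
    """Per-subject alpha calibration against the splenium reference."""

    alphas: np.ndarray          # per-subject alpha
    alpha: float                # cohort value: median over subjects
    g_star: float
    roi_summary: dict           # mean MT / FICVF / FISO over subjects


def calibrate_cohort(roi_mt, roi_ficvf, roi_fiso,
                     g_star: float = 0.70,
                     literal_eq1: bool = False) -> CalibrationResult:
    """Calibrate alpha per subject and pool by the cohort median."""
    roi_mt = np.atleast_1d(np.asarray(roi_mt, dtype=float))
    roi_ficvf = np.atleast_1d(np.asarray(roi_ficvf, dtype=float))
    roi_fiso = np.atleast_1d(np.asarray(roi_fiso, dtype=float))
    alphas = np.array([
        calibrate_alpha(mt, fi, fw, g_star=g_star, literal_eq1=literal_eq1)
        for mt, fi, fw in zip(roi_mt, roi_ficvf, roi_fiso)
    ])
    return CalibrationResult(
        alphas=alphas,
        alpha=float(np.median(alphas)),
        g_star=g_star,
        roi_summary={"MT": float(roi_mt.mean()),
                     "FICVF": float(roi_ficvf.mean()),
                     "FISO": float(roi_fiso.mean())},
    )


def sensitivity_scan(mt, ficvf, fiso,
                     roi_mask=None,
                     g_star_grid=(0.68, 0.69, 0.70, 0.71, 0.72),
                     literal_eq1: bool = False) -> np.ndarray:
    """Pairwise Pearson correlations of g maps across reference values.

    For each grid reference value, alpha is recalibrated from the reference
    ROI (``roi_mask`` boolean array; the whole map if None) and the map
    recomputed; correlations are taken across voxels valid in all maps.
    Degenerate (constant) maps yield NaN correlations.
    """
    g_star_grid = tuple(g_star_grid)
    if len(g_star_grid) < 1:
        raise ValueError("g_star_grid must be non-empty")
    mt = np.asarray(mt, dtype=float)
    ficvf = np.asarray(ficvf, dtype=float)
    fiso = np.asarray(fiso, dtype=float)
    mask = np.ones(mt.shape, bool) if roi_mask is None else np.asarray(roi_mask, bool)
    maps = []
    for gs in g_star_grid:
        alpha = calibrate_alpha(float(mt[mask].mean()), float(ficvf[mask].mean()),
                                float(fiso[mask].mean()), g_star=gs,
                                literal_eq1=literal_eq1)
        maps.append(np.ravel(compute_g(mt, ficvf, fiso, alpha,
                                       literal_eq1=literal_eq1)))
    maps = np.vstack(maps)
    valid = np.isfinite(maps).all(axis=0)
    if valid.sum() < 3:
        raise ValueError("need at least 3 jointly valid voxels")
    maps = maps[:, valid]
    k = len(g_star_grid)
    corr = np.full((k, k), np.nan)
    # degenerate (numerically constant) maps have undefined correlation
    sds = maps.std(axis=1)
    sds[sds <= 1e-12 * np.maximum(1.0, np.abs(maps).max(axis=1))] = 0.0
    for i in range(k):
        for j in range(k):
            if i == j:
                corr[i, j] = 1.0 if sds[i] > 0 else np.nan
            elif sds[i] > 0 and sds[j] > 0:
                corr[i, j] = float(np.corrcoef(maps[i], maps[j])[0, 1])
    return corr
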
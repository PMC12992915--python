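# Methods

This note documents the models, the numerical choices, and the limits of
what the test suite demonstrates.

## Segment-wise repeated-measures ASCA

**Model.**  For one tract segment, each metric is standardized (z-scored
over all subject-session observations of that segment, ddof = 1; the
means/SDs are retained for exact de-standardization and for projecting
individual subjects).  Each standardized metric is fitted with a linear
mixed model `outcome ~ time + (1 | subject)` with the baseline session as
the reference level, i.e. two fixed session effects and a random subject
intercept.  The fixed time effects of all metrics form an observation-by-
metric effect matrix (three unique rows on a complete three-session
panel, the baseline row identically zero).

**Decomposition.**  The effect matrix is decomposed by SVD *without*
column centering: under reference coding the baseline session maps to the
origin, so PC trajectories start at zero by construction.  Explained
variance fractions are squared singular values over their sum.  The PCA
sign is arbitrary; we fix it so the metric with the largest absolute PC1
loading is positive, and every bootstrap replicate is sign-aligned to the
point estimate by the sign of the loading dot product.

**Estimation paths.**  On a balanced complete panel the GLS fixed-effect
estimator of the random-intercept model equals the session-mean
differences exactly (the design matrix is balanced across the compound-
symmetric blocks), so point estimates and bootstrap replicates use that
closed form; the equality against a REML `MixedLM` fit is asserted in the
tests.  Unbalanced or incomplete panels go through `statsmodels` MixedLM
(REML) per metric; missing cells are handled by the likelihood, without
imputation.  A variance component estimated at the zero boundary is
flagged, not raised.

**Uncertainty.**  Cluster bootstrap: subjects are resampled with
replacement and the full pipeline (standardization, mixed models, SVD) is
rerun per replicate — B = 1000 by default, reduced in simulation-heavy
tests.  Intervals are BCa: bias correction from the bootstrap
distribution (ties half-weighted), acceleration from a leave-one-subject-
out jackknife.  Degenerate bootstrap distributions collapse to point
intervals; when every replicate falls on one side of the point estimate
the interval falls back to plain percentiles.  Replicates whose fit fails
(e.g. a zero-variance metric after resampling) are dropped and counted;
more than 10% failures is an error.

**Classification.**  A segment is *plastic* when (i) the MRI1 and MRI2
PC1-score intervals overlap (stable control interval), (ii) the MRI3
interval is disjoint from MRI1's, and (iii) disjoint from MRI2's.  On a
null cohort this triple CI-overlap rule is strongly conservative: the
measured plastic rate is 0 of 180 simulated null segments in the test
configuration (bound asserted at <= 1%).

**Known bias.**  Because the PC1 score of the post-training session is a
norm-like functional of noisy per-metric effects, it is biased away from
zero when many metrics carry no signal; BCa corrects the bootstrap's
internal bias but not the estimator's own.  In coverage simulations the
95% score interval covers the generative score at ~95% with a 2-metric
panel but degrades to ~87-89% with six additional null metrics.  The
coverage calibration test therefore uses the bivariate design, which
isolates the interval machinery; users should read post-training score
magnitudes on noisy panels as slightly inflated.

## Aggregate g-ratio

`g = sqrt(1 - MVF/FVF)` with `MVF = alpha*MT`,
`AVF = (1 - alpha*MT)(1 - FISO)*FICVF`, `FVF = MVF + AVF` — the standard
aggregate formulation in which the myelin fraction is referred to the
total fiber volume.  A `literal_eq1` flag computes the variant
`sqrt(1 - MVF/AVF)` (myelin referred to the axonal volume only), which
arises when the denominator omits the myelin compartment; the two agree
only in the unmyelinated limit, and the default is the formulation
consistent with the g-ratio literature and with a plausible calibration
factor (alpha ~ 0.10 at splenium-typical MT ~ 3.5 p.u.).

Calibration inverts the expression in closed form: with
`A0 = (1 - FISO)*FICVF`,
`alpha*MT = A0(1 - g*^2) / (A0(1 - g*^2) + g*^2)`; the round trip is
exact to machine precision.  Alpha is calibrated per subject against the
splenium reference `g* = 0.70` and pooled by the cohort **median**.
Invalid voxels (`alpha*MT >= 1`, zero fiber volume) become NaN, never
clamped.  The sensitivity scan recalibrates alpha per grid reference
value (0.68-0.72 by default) and correlates the resulting maps across
jointly valid voxels; because the reparameterization is smooth and
monotone, correlations are near 1 for heterogeneous tissue.

MT is treated as a percent-units scalar; alpha absorbs the unit choice.
ROI extraction is out of scope — the calibration consumes ROI means.

## Learning curves

Session-mean balance times are fitted with `y = a * s^b` by nonlinear
least squares, initialized from the log-log linear fit (exact on
noise-free power-law data) with two fallback starts; a 3-parameter form
`y = c + a * s^b` is available.  Session indices are 1-based.  The group
test is a one-sample t of the exponents against zero, one-sided (greater)
— improvement implies b > 0 — with the two-sided p also reported.
Zero-variance exponents make the test undefined (NaN), not an error.

## Brain-behavior pooling

Interval change scores are `score(MRI3) - score(MRI1)` and
`score(MRI3) - score(MRI2)`; each is Spearman-correlated (average ranks
on ties) with the per-subject learning exponent.  The two correlations
are pooled by the Olkin-Pratt first-order unbiased correction
`G_i = r_i (1 + (1 - r_i^2)/(2(n_i - 3)))` with sample-size weights, and
the CI/p use the per-study variance `(1 - G^2)^2/(n_i - 1)` with
`V = sum(w^2 v)/(sum w)^2` and a normal approximation.  The one-sided p
follows the hypothesized direction — the sign of the group PC1
trajectory change, fixed before computing p.

The two intervals share the post-training session and are dependent;
fixed-effect pooling ignores this, so the pooled interval is
anti-conservative.  Measured coverage at n = 24 with interval correlation
0.5 and true Spearman 0.4 is ~85-87% (and ~90-94% even for independent
intervals, reflecting the normal approximation without a Fisher
transform at this n).  The test suite computes and bounds this observed
coverage rather than asserting the nominal level.

Neighbor merging: maximal runs of adjacent plastic segments whose PC1
loadings have pairwise |cosine| >= 0.9 are merged by averaging raw metric
values across the run per (subject, session, metric), then refitting the
segment model on the averaged profile.

## Monte Carlo multiplicity null

Each of 2,320 segments (29 tracts x 80 centrally retained of 98
segments) gets k = 4 criterion z-scores from the one-factor
equicorrelated construction `z_j = sqrt(rho) W + sqrt(1-rho) eps_j`
(exact for uniform rho = 0.5, unit marginals).  A segment is a false
positive when `min_j |z_j| > 1.96` — all criteria simultaneously
"significant", deliberately conservative in treating the control-interval
*non*-significance requirement as a fourth significance criterion.  The
familywise p is the proportion of 10,000 iterations whose count reaches
the observed count (>= rule, no continuity correction).  A semi-analytic
oracle integrates the conditional pass probability over the shared factor
(per-segment q = 1.50e-3, expected count 3.47), under which the count is
Binomial(2320, q) and P(count >= 9) = 0.0094; the simulation reproduces
this within Monte Carlo error in a few seconds (chunked vectorization).

## Network stage

PCA of the subjects-by-sections change matrix runs on the correlation
matrix, unrotated, complete rows only, constant columns excluded; the
component sign makes the mean loading positive.  Diagnostics: KMO from
anti-image partial correlations (scaled inverse correlation matrix;
exactly 0.5 for p = 2), Bartlett's sphericity
`chi2 = -(n - 1 - (2p+5)/6) ln det(R)` with df = p(p-1)/2, the
det(R) > 1e-5 multicollinearity floor, and Horn parallel analysis (mean
criterion over simulated uncorrelated Gaussian data of identical shape,
retention stopping at the first non-exceeding rank).

Robust regression is MM: fast-S search (elemental subsets plus an OLS
start, short IRLS refinements under the 50%-breakdown bisquare
c0 = 1.5476, coarse M-scale during the search and a polished scale for
the winner), then a bisquare M-step at 95% Gaussian efficiency
(c = 4.685) holding the S-scale fixed.  Coefficient intervals come from a
case-resampling bootstrap (BCa) whose replicates are warm-started from
the full-sample solution.  Robust R2 and the omnibus pseudo-F are
deviance-based (`D = sum rho(r/s)` at the fixed scale, compared against a
robust intercept-only fit at the same scale, F(q, n-p) reference); these
definitions are package choices, as no single convention is universal.
For multiple-predictor models the report emphasizes the omnibus test and
the condition number; individual coefficients are computed but
de-emphasized under multicollinearity.  LOOCV reports MSE, RMSE and
`1 - SSE_model/SSE_null` against per-fold training-mean null predictions.

The change-score interval feeding the network matrix defaults to the
training interval (MRI3 - MRI2) and is configurable to MRI3 - MRI1.

## Synthetic cohort generator

The generator emulates a controlled within-subject design: 24 subjects,
three sessions four weeks apart, a no-intervention control interval and a
training interval, 29 bundles x 98 segments x 8 metrics.  A metric value
is `native mean + native scale * (subject intercept + effect + AR(1)
residual)`: Gaussian subject intercepts (SD 0.5 z) shared across
sessions, stationary AR(1) residuals along segments (phi = 0.7, SD 0.5 z)
for spatially smooth profiles, and training effects that apply a signed
unit-norm metric loading pattern at configured segments at the
post-training session only (control-interval magnitude 0 by default).
Subject effect magnitudes are `group_magnitude + subject_sd * d_i` with a
standard-normal latent `d_i` shared across effect templates, so
distributed effects cohere within subject.  Native means/scales are
plausible adult white-matter values (e.g. FISO 0.10 +/- 0.02, MT
3.5 +/- 0.3 p.u., R2* 20 +/- 2 /s); working in z-units underneath means
downstream standardization recovers injected effect sizes.

Behavior: per-trial balance times `a_i * s^{b_i} + noise`, truncated to
the 30 s trial duration, 8 sessions x 15 trials; `log b_i ~
N(log 0.3, 0.35^2)` puts the group exponent near 0.3 with enough spread
that a 24-subject one-sample t is strongly significant, matching robust
group learning.  Exponents are coupled to the subjects' effect
magnitudes through a Gaussian copula (Blom normal scores of the magnitude
ranks, latent Pearson correlation `2 sin(pi rho_s/6)`), hitting a target
Spearman rho (default 0.5) exactly in expectation; an achieved rho far
from the target triggers a warning.  Cortical change is
`gamma * m_i + Normal(0, sd)`.

One master seed; child seeds for the profile, behavior and cortical
components are spawned deterministically and recorded.

**What the generator does not emulate:** voxel-level signal formation,
registration error, session-level scanner drift, spatially varying
metric covariance, non-Gaussian physiological outliers, or real
between-metric correlation at baseline (metrics are independent under
the null).  Passing tests therefore demonstrate statistical correctness
and calibration of the pipeline under its stated assumptions, not
performance on real MRI data.

## Problem sizes in the test suite

Simulation-based tests use reduced but statistically meaningful sizes
chosen as a design point: bootstrap B = 150-400 with 24-subject cohorts,
200 replicate cohorts for coverage calibration, 150-400 replicates for
robust-regression calibration, 10,000 iterations for the Monte Carlo
null (its headline setting), and 300 REML replicates for variance-
component recovery.  The interfaces accept the full-scale settings
(B = 1000, 29 x 80 segments) unchanged.

## Interfaces

This is a library: the model/results classes and
`scripts/acceptance.py` are the interface; no shell CLI is shipped.
Optional NIfTI I/O for g-ratio maps can be layered on via nibabel;
the core functions operate on arrays and data frames.
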
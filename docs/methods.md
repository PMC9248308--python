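# Methods

## The reliability model

`icedmri` decomposes repeated quantitative-MRI measurements into four
orthogonal variance compartments.  A scan-rescan study is described by a
`StudyDesign`: an ordered list of measurement occasions, each belonging
to one *day* and one *session* (a contiguous stay in the scanner without
repositioning; sessions are nested in days).  The default design mirrors
a two-day protocol with four occasions: two back-to-back measurements on
Day 1 sharing one session, and two measurements on Day 2 separated by
repositioning, hence in two different sessions.  Repositioning implies a
new prescan (RF amplitude, centre frequency, B0 shim), which is exactly
what the session compartment is meant to capture; this is also why the
Day-1 pair must share a session factor — it is the only structure under
which the session variance is identified from the Day-1 within-pair
covariance.

For person *p* and occasion *o* the model is

    y[p, o] = mu[o] + T_p + D_{p, day(o)} + S_{p, session(o)} + E_{p, o}

with independent zero-mean Gaussian effects of variances Var T (stable
between-person differences), Var D (day-specific error), Var S
(session-specific error, i.e. the repositioning effect) and Var E
(residual error).  Equivalently, each person's occasion vector is
multivariate normal with a saturated mean structure and covariance

    Sigma = VarT * J + VarD * C_day + VarS * C_sess + VarE * I,

where J is all-ones and the C matrices are binary co-membership
indicators derived from the design.  The derived reliability summaries
are

* **ICC** = VarT / (VarT + VarD + VarS + VarE): test-retest reliability
  of a single measurement.  Because results are reported as proportions
  rescaled to sum to one, the rescaled VarT *is* the ICC.
* **effective error**: the error variance of the best linear unbiased
  (precision-weighted) composite of all k occasions,
  1 / sum(inv(E)) with E the error part of Sigma.  With residual error
  only this reduces to VarE / k.  The verbal "single residual error
  term of the whole design" fixes only that residual-only case; the
  precision-weighted composite is this package's definition in the
  general case, and validation against published values uses only
  residual-only rows, where every sensible definition coincides.
* **ICC2** = VarT / (VarT + effective error): reliability of the whole
  k-occasion design at the construct level.

## Estimation

Full-information Gaussian ML.  The saturated occasion means are profiled
out analytically (their ML values are the occasion-wise sample means),
reducing the log-likelihood to a function of the divisor-N sample
covariance S:

    loglik = -N/2 (k log 2pi + log|Sigma| + tr(S Sigma^{-1})).

The four components are maximised under a lower bound of 0.0001 each
(applied on the scale of the fitted data) with L-BFGS-B using exact
analytic gradients; the objective is internally rescaled by the mean
diagonal of S, which makes the optimizer's trajectory — and therefore
proportions, ICC, ICC2, the component tests and RMSEA — invariant under
affine transforms y -> a*y + b of the data whenever no estimate is at
the bound.  Start values are method-of-moments: the mean cross-day
covariance estimates VarT, the day-sharing (session-distinct) covariance
minus VarT estimates VarD, the session-sharing covariance minus both
estimates VarS, and the mean variance minus all three estimates VarE,
clipped to the bounds.  Because the profiled objective can be multimodal
in very small samples, fits with fewer than 30 persons also try two
deterministic fallback starts (equal split; residual-dominant) and keep
the best; non-convergence triggers up to three jittered restarts and is
always reported via a `converged` flag, never silently.

An optional `standardize=True` mode divides the values by their grand SD
before fitting.  Proportions, ICC, ICC2 and all tests are unaffected
when the bound is inactive; the mode matters for modalities whose
absolute variance is far below 1 (e.g. MT-saturation in percent units,
with total variance of order 1e-3), where a bound of 1e-4 on the raw
scale would otherwise swallow genuinely small components.  This mirrors
the common practice of standardizing before structural-equation fitting.

### Significance tests

VarT, VarD and VarS are tested by likelihood-ratio tests against null
models refit with the component pinned at zero (1 df).  The naive
chi-square(1) p-value is the default; because the null value lies on
the boundary of the parameter space, an optional 50:50
chi-square(0)/chi-square(1) mixture p-value is available
(`boundary_correction=True`), which simply halves a positive-statistic
p-value.  VarE cannot be tested this way — without residual error the
model covariance is singular — so it gets a Wald test, (estimate/SE)^2
with the SE taken from the inverse observed information.  The observed
information is computed from exact trace formulas for a linearly
structured covariance (not finite differences); the test suite checks
it against a numerical Hessian.

### Exact-fit statistics

The model chi-square is (N-1) times the ML discrepancy against the
saturated covariance model, F = (2/N)(loglik_saturated - loglik_model);
df = k(k+1)/2 minus the number of free components (6 for the default
design with all four free); RMSEA = sqrt(max(chisq - df, 0)/(df (N-1))),
zero whenever chisq <= df.  The (N-1) convention is recorded in the
output metadata of every run.

### Bootstrap confidence intervals

ICC and ICC2 intervals are percentile intervals from a nonparametric
bootstrap resampling persons with replacement (default 1000 replicates,
95% level), driven by one explicit seed.  Replicates whose refit does
not converge are dropped and counted; more than 20% drops is an error.
Percentile intervals can occasionally exclude the point estimate; the
tests assert bracketing only for the vast majority of seeds.

## Reporting conventions

Variance estimates are reported rescaled to sum to one.  Estimates that
sit exactly at the lower bound are shown as 0.000 in rescaled output
tables (the bound is a numerical floor, not a substantive estimate),
while raw estimates retain the bound value.  Tables print proportions
and ICCs with three decimals.

## Signal estimation

* **Joint multi-echo decay fit** (the ESTATICS approach): all echoes of
  up to three contrast-weighted FLASH trains (T1w, PDw, MTw) enter one
  ordinary-least-squares fit of log-signal on echo time with a single
  common slope (-R2*) and one intercept per contrast; intercepts are
  exponentiated back to the signal scale, the slope is returned in 1/s.
  Unweighted OLS in the log domain is used deliberately; no SNR
  weighting.  On noiseless mono-exponential input the fit is exact to
  machine precision for any positive parameter set.
* **Ernst equation**: S = A sin(a)(1 - E1)/(1 - cos(a) E1),
  E1 = exp(-TR R1).  Dual-flip-angle R1 recovery solves the two Ernst
  equations with common amplitude by a bracketed Brent root of the
  signal-ratio equation on R1 in (1e-4, 100) 1/s — an exact numerical
  inversion; the classical small-angle rational approximation is
  provided separately (`dual_flip_angle_r1_approx`) for comparison
  only.  Absence of a sign change in the bracket (inconsistent inputs)
  is an error.
* **PD calibration**: the global proton-density scale is not
  identifiable without an external standard, so maps are rescaled so
  the white-matter mean equals 69 percent units.

Protocol constants follow the acquisition the package emulates: TE
2.34–14.04 ms in six equidistant echoes for T1w/MTw with two extra PDw
echoes at 16.38 and 18.72 ms; TR 24.5 ms; flip angles 21° (T1w) and 6°
(PDw/MTw).

## Synthetic data

The generator inverts the generative model above, drawing person, day,
session and residual effects from independent Gaussians — heavy-tailed
options are deliberately excluded since the fitted likelihood is
Gaussian.  All randomness flows from one explicit seed per call.  The
default study spec mirrors the motivating study: 15 persons, the
four-occasion design, occasion means at whole-brain gray-matter levels
(MT 0.874 p.u., PD 80.61 p.u., R1 0.622 1/s, R2* 16.9 1/s) and
gray-matter-like MT proportions (0.883/0.000/0.003/0.114).  The default
absolute variance scale (6.5e-4 total for MT, scaled by the squared
mean for other modalities) was chosen once so that the implied
within-person coefficient of variation lands near the ~1% reported for
whole gray matter.  Voxel-map generation applies the same model per
voxel with spatially varying (or constant) component fields, fills
out-of-mask voxels with NaN, and stays deliberately desk-scale.

What the generator does *not* emulate: Rician magnitude noise, motion
and susceptibility artifacts, B0/B1 field inhomogeneity, spatial
autocorrelation between voxels, and registration error.  Passing
recovery tests therefore demonstrates correctness of the estimator
under its own assumptions, not robustness to real-scanner artifacts.

## Problem sizes used in the checks

Deterministic worked examples run on printed three-decimal variance
decompositions and are exact to rounding.  Parameter-recovery checks
use 200 replicates of 100 persons; bootstrap coverage uses 200
replicates with 199 bootstrap samples each at 100 persons — sizes
chosen to keep Monte-Carlo error well below the asserted tolerances
while the whole suite stays comfortably fast on one CPU.  Voxel-wise
tests use small phantoms (a few hundred voxels); the voxel loop is
order-independent by contract, so larger volumes only cost time.

## Known limitations

* The model is a single-group, complete-data design; missing cells are
  a hard error by default with listwise deletion as the only option.
* No REML: variance estimates carry the usual ML small-sample bias
  (order 1/N), visible in the degenerate-data tests.
* The LRT null distribution on the boundary is approximated (naive or
  50:50 mixture); neither is exact at small N.
* ICC2 for designs with non-zero day/session variance depends on the
  effective-error definition; published values for such rows are not
  exactly reproducible from rounded printed components, and the package
  makes no attempt to force agreement.
* General structural-equation paths, D-study extrapolation beyond ICC2,
  registration, segmentation and smoothing are out of scope.
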
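# Methods

`kratkit` implements an end-to-end analysis for accelerometry-based
behavior classification and diel activity budgets in small nocturnal
mammals, exercised on synthetic data with known ground truth.  This note
documents the models, the conventions that were genuinely open choices,
the numerical decisions, and what the synthetic experiments do and do not
demonstrate.

## Behavioral vocabulary and data model

Behavior is a four-class ethogram — motionless, travel, foraging,
grooming — serialized as lowercase strings.  Acceleration is tri-axial at
25 Hz in units of g, with a hard sensor range of ±10 g; a deployment is a
uniformly sampled trace (timestamps implied by `t0 + i/fs`).  All
timestamps are UTC internally; site-local time enters only through the
ephemeris and the night grouping.  A *night* is identified by the local
date of its preceding noon (noon-to-noon), so one continuous dark period
is never split across two night ids.

## Synthetic-data generator

The generator is first-class, tested code; it defines the study
conditions for every downstream check.

**Behavior dynamics.** Bout sequences are sampled from a continuous-time
Markov chain over the four behaviors whose generator matrix switches with
the diel light phase (piecewise-homogeneous; the phase is sampled on a
one-minute grid and, by memorylessness, the sojourn clock restarts at
phase boundaries).  The default profile is nocturnal: day-side phases
(morning, day, evening) hold ≥ 99% motionless occupancy with travel
occupancy well under 5%; dusk and evening twilight are a ramp; night,
morning twilight and dawn are fully active with elevated travel and
foraging.  Stationary occupancies are available in closed form from each
generator and serve as ground truth for budget checks.  CTMC sojourns
shorter than 2 s are merged into the preceding bout so schedules satisfy
a minimum-bout-length contract.

**Acceleration signals.** Each bout renders as a fixed gravity
orientation (per behavior, with a small per-bout orientation perturbation
representing posture variability) plus sinusoidal bursts: hop-like 4–8 Hz
oscillation at 0.8–1.6 g for travel; slower 2–4 Hz rhythms at ~0.1–0.45 g
for foraging and grooming, whose frequency, amplitude, duty-cycle and
posture ranges deliberately overlap so the two classes remain partially
confusable — the confusion structure observed in real data.  The
oscillator carries mild cumulative phase jitter (cadence variability), so
the sampled sinusoid is not stroboscopically locked to the 25 Hz grid.
Gaussian noise is added and samples are clipped to ±10 g (clipping
logged).  These signatures are qualitative stand-ins chosen for realism
of structure (class-conditional ODBA ordering motionless < grooming ≈
foraging < travel), not estimates of any species' real dynamics.

**Covariates.** Nightly moon illumination comes from the ephemeris;
temperature (26 ± 3 °C), wind (3 ± 1.5 m/s) and relative humidity
(40 ± 12 %RH) are independent Gaussian draws around configurable
seasonal means approximating desert-grassland summer nights.  Injected
covariate effects (e.g. a humidity→foraging slope) are recorded in a
ground-truth sidecar.  A separate budget-level generator draws
(individual, night) cells directly from a weighted-binomial mixed model
with known coefficients and random-intercept SDs (defaults 0.5 on the
logit scale, ~60 windows per cell); its default injected humidity effect
is a logit slope of 0.5 per SD of humidity — a moderate effect mirroring
the kind of weather dependence the pipeline is meant to detect.

**What the generator does not emulate:** orientation drift and
attachment artifacts, terrain/microhabitat effects, biomechanically
realistic hop kinematics, autocorrelated weather, or behavior-dependent
missingness.  Passing tests therefore demonstrate that the pipeline's
machinery is correct and calibrated under a known generative model, not
that any particular accuracy will be attained on field data.

## Window features

Traces are tiled into non-overlapping windows (1, 2, 3, 6, 9 s; trailing
partial windows discarded; no sliding stride, so no sample is reused
between training and test halves).  The 16 summary statistics are laid
out per axis as a 41-number vector (documented order in
`features.FEATURE_NAMES`).  Fixed conventions, since the upstream
feature definitions are not published to this level of detail: moments
use the n-denominator; the static component removed for DBA is the
window's own per-axis mean (windows are ≤ 9 s); mean DBA is the mean
absolute deviation per axis; ODBA is the *mean* over samples of
|DBAx|+|DBAy|+|DBAz| so values are comparable across window sizes;
percentiles interpolate linearly; mean-diff/std-diff are the mean
absolute value and SD of first differences; wave amplitude is max−min;
line crossings count sign changes of the DBA sequence with zeros
inheriting the previous sign; Pearson correlations involving a
zero-variance axis are defined as 0 (flagged) to keep classifier inputs
finite.  A reduced set {per-axis mean, per-axis SD, ODBA} is also
exposed.  Labels transfer from annotation bouts only when a window lies
inside a single bout after ±1 s of alignment slack (scores are
time-matched to the logger only to within a second); straddling windows
stay unlabeled.

## Classification protocol

Classes are balanced by subsampling every class without replacement to
the rarest class, then split 50/50 into train/test.  The split is
stratified by class — a deliberate strengthening of "random 50%" that
guarantees all classes appear on both sides at small n.  Balancing
happens before splitting, following the order of the original protocol.
Candidates are a linear SVM (standardized with train-only statistics),
a decision tree, and a random forest, all at library-default
hyperparameters with pinned seeds.  Metrics come from the 4×4 confusion
matrix; per-class accuracy is one-vs-rest (TP+TN)/total.  The selected
model maximizes the unweighted mean of macro accuracy, macro precision
and macro recall; ties break by macro recall, then smaller window, then
lexicographic spec label.  Windows from all individuals are pooled before
splitting.

## Ephemeris

Solar position uses the standard low-precision theory (mean longitude +
equation of center, leading nutation/aberration correction); lunar
position uses the dominant periodic terms of the lunar theory (27
longitude/distance terms, 20 latitude terms, planetary additive terms)
with topocentric parallax.  The TT−UT offset uses the long-term
parabolic fit.  All altitudes are geometric (airless); the conventional
−0.833° refraction altitude applies only to reported sunrise/sunset
instants (configurable).  Verified accuracy against an independent
fuller implementation (segmented TT−UT fit, explicit nutation series,
rigorous topocentric transformation — itself anchored to published
worked-example positions and almanac lunation instants): sun altitude
within 0.005°, moon altitude within 0.02°, illuminated fraction within
1e-4, rise/set crossings within seconds — far inside the documented
0.5°/0.02/5-minute contracts.

The eight diel phases: below the horizon, bands at 0–6° (dawn/dusk),
6–18° (twilights) and > 18° depression (night), with the morning/evening
side decided by the sign of the altitude rate; above the horizon, the
first hour after geometric sunrise is morning, the last hour before
geometric sunset is evening, day otherwise.  Band bounds are half-open
(lower bound inclusive); boundary instants are bisected to ~5 ms so a
1-second scan never sees an out-of-order phase.  Moon intensity is
categorical: < 0.33 low, 0.33–0.66 medium (both boundary values
inclusive, i.e. 0.33 and 0.66 are medium), > 0.66 high.  The nightly
continuous moon value is the illuminated fraction at local mean solar
midnight of the night.  Polar day/night is an explicit unsupported-
latitude error.

## Budgets

Each predicted window joins the light phase containing its midpoint
(deterministic and unbiased for windows straddling boundaries).  Budgets
are counts and proportions per grouping cell, kept at the (individual,
night, phase) grain — proportions within a cell sum to 1 and counts
conserve total classified time; the mixed models then weight cells by
their window counts rather than pooling across individuals first, which
preserves the random-effect structure.  The moonlight analyses restrict
to phases with the sun below the horizon (dusk through dawn); an
optional toggle drops nights with any precipitation (cloud-cover proxy).

## Mixed models

The response for a behavior is its proportion of windows per
(individual, night) cell.  Candidate families are gaussian, poisson,
binomial and gamma; infeasible candidates for a given response (zeros
for gamma, non-counts for poisson, missing trial counts for binomial)
are skipped with a logged reason, the rest are fitted with identical
fixed/random structure, and the minimum-AIC fit is kept.  Because the
binomial likelihood is a pmf on counts while the others are densities on
proportions, family AICs are compared on a common scale via the change
of variables density(p) = trials × pmf(successes); both the comparable
and raw AICs are persisted.  When binomial is selected, proportions are
modeled as weighted binomial counts (successes = behavior windows,
trials = cell windows).

Estimation is maximum likelihood with crossed random intercepts for
individual and night (random intercepts only).  For fixed variance
parameters the joint penalized likelihood in (β, u) is maximized by
damped Newton iteration; the Laplace criterion — exact for the gaussian
family — is then optimized over the log-variance (and log-dispersion)
parameters by L-BFGS-B from two starts with a Nelder–Mead polish, since
the profile surface can have flat ridges where a variance component
collapses to its boundary (bounds at e^−12).  Standard errors for β come
from the Schur complement of the joint information at the mode,
conditional on the variance estimates — the same convention as the
standard mixed-model packages, against which the engine is cross-checked
in the test suite (gaussian: statsmodels MixedLM, agreement to ~1e-5 in
log-likelihood; binomial: R glmmTMB, agreement to ~1e-3 in coefficients
and SEs on a frozen dataset).

Fixed-effect terms are tested with Wald chi-square statistics (all
contrasts of a term jointly; p from the upper tail), collinearity is
screened with VIFs (1/(1−R²_j), intercept included, categorical
predictors reported per contrast, exact collinearity reported as
infinite), and model fit is summarized by the conditional R² —
(var_fixed + var_random)/(var_fixed + var_random + var_residual) on the
link scale with the family-appropriate residual term: the dispersion for
gaussian, π²/3 for logit-binomial, log(1 + 1/mean(μ)) for log-Poisson,
log(1 + dispersion) for log-Gamma.  No multiple-testing adjustment is
applied across behaviors (matching common practice in this analysis
style); pairwise contrasts are reported unadjusted.  Wald tests are
asymptotic: at the study-sized design (14 individuals × 20 nights) the
realized type-I error for a night-level covariate runs slightly above
nominal (~0.07 at nominal 0.05 over large simulations), which is a
property of the test itself, not of the implementation — the engine
matches glmmTMB on the same data.

## Problem sizes used in the checked experiments

Chosen to exercise every stage at desk scale: classifier checks pool
three 14 h deployments (≈ 25,000 6-s windows, > 300 per class before
balancing) over a window grid of {2, 6} s; determinism runs the full
chain twice on two 26 h deployments at one window size; calibration uses
400 null replicates at 14 × 20 and power 50 replicates at 14 × 40 nights
(the covariate varies nightly, so "doubling the data" doubles the night
axis).  Default pipeline configuration mirrors a realistic field study
(14 individuals, ~5-night deployments) and is correspondingly heavier to
run.

## Known limitations

* The ephemeris targets mid-latitudes; polar day/night is rejected, and
  refraction/parallax refinements beyond the documented level are out of
  scope.
* Non-gaussian GLMM inference conditions on estimated variance
  components (no REML analogue, no Kenward–Roger-style small-sample
  correction), so Wald tests at very small designs are mildly liberal.
* Predictions are per-window with no temporal smoothing (no HMM/CNN
  post-processing), and probability calibration is not attempted.
* Synthetic signal parameters are structural placeholders; absolute
  classifier metrics on synthetic data say nothing quantitative about
  field data.
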
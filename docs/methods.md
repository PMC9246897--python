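# Methods

`vigilant_ensemble` predicts a longitudinal vigilant-attention outcome
(the LRM-50 score from a brief psychomotor vigilance test) for a small
cohort of individuals on long missions, from irregularly and discordantly
sampled covariates: cabin environment sensors, self-rated psychological
state, sleep diaries, medication reports and person-level traits.  This
note documents the models, the synthetic cohort generator that stands in
for the restricted flight data, the numerical choices, and what the test
suite does and does not establish.

## Outcome scoring

A test bout is a sequence of reaction times (RT, ms) plus premature
presses.  Derived metrics:

- **Lapses / false starts.** RT ≥ 355 ms counts as a lapse; responses
  below 100 ms, and presses without a stimulus, count as false starts.
  Both thresholds are configuration — they are operational conventions for
  the brief test, not constants of nature.  Whether sub-threshold RTs join
  the false-start category is switchable (default: yes).
- **OPS** = 1 − (false starts + lapses)/valid stimuli ∈ [0, 1].
- **LRM-50.** The RT axis is cut into 49 intervals plus a false-start
  category (50 categories).  Each category carries a likelihood ratio: the
  relative frequency of responses in that category under a sleep-deprived
  reference distribution divided by that under a rested one.  A bout's
  score is the **sum of the log ratios** of its stimuli (equivalently the
  log of the product, but computed as a sum for numerical stability).
  Zero means the bout is equally likely under either state; lower is more
  rested-like.  Interval edges are quantiles of the pooled valid RTs, and
  0.5 pseudo-counts per category keep every ratio finite and positive.
  The canonical reference distributions are not redistributable, so the
  package ships `default_lr_table()` — a **synthetic** table built from
  seeded lognormal draws (rested median 250 ms, σ_log 0.18, 0.5% premature;
  deprived median 300 ms, σ_log 0.30, 4% premature).  Scores against it
  are internally consistent and sign-correct but not comparable to
  published values; any user-supplied table in the same 50-category format
  can replace it.
- **Standardized LRM-50** is (x − mean)/SD per participant.  By default
  the scaling statistics come from a caller-designated source window (use
  the training window inside cross-validation to avoid test-set leakage);
  passing the full series reproduces global scaling.

## Sensor fusion

Rules for attaching environmental values to each self-test, in order of
preference, with a provenance flag per value (`observed`, `interpolated`,
`carried-forward`, `imputed-mean`):

1. Daily variables (radiation mGy/day, station occupancy) join by UTC
   calendar day.
2. Sub-hourly variables (temperature, CO₂, O₂, noise) use the mean over
   the clock hour containing the test; noise always uses the energetic
   mean 10·log₁₀(mean(10^(dBA/10))) because decibels are logarithmic.  Any
   hour with ≥ 1 sample counts as observed.
3. Temperature and noise are per-module: a test in Node 2 or the US Lab
   uses that module's sensor; otherwise a 0.75/0.25 Node 2/US Lab blend.
   If one side is missing, the available side is used (provenance
   downgraded).
4. Missing hours fall back to LOESS — local *linear* regression with
   tricube weights over the α = 0.1 nearest fraction of the series
   (`statsmodels.lowess`, robustness iterations off).  Temperature gets
   three separate interpolations (Node 2, US Lab, blended).  Degree 1 is
   exact on linear streams, which the tests exploit.  On very short series
   the window is floored at 3 points (α effectively raised), otherwise the
   fit is refused with a pointer to a larger α.
5. Noise is too sparse for LOESS.  Each ~24-h dosimeter session is reduced
   to a daytime (07:00–22:59 UTC) and nighttime (23:00–06:59 UTC)
   energetic mean; a test's value is interpolated linearly between the
   bracketing sessions' same-phase means, held constant beyond the first
   and last session (linear extrapolation from two sparse knots is
   unbounded and was rejected).
6. Sleep-diary fields are carried forward from the participant's last
   report.

Tests outside every stream's time range (±1 day) are dropped with a count
in `fused.attrs["n_excluded"]`.

## Derived predictors

- **Stress/fatigue composite**: correlation-matrix PCA of the seven
  11-point ratings, using pairwise-complete observations because two
  ratings are track-specific (workload is asked only in the evening, sleep
  quality only in the morning), so no row is complete.  The score is the
  PC1-loading-weighted average of the raw ratings, sign-anchored so higher
  = more stressed; rows with missing ratings renormalize the weights over
  what is observed.
- **Medication flags**: case-insensitive keyword lexicon →
  pain / sleep-aid / decongestant / antihistamine booleans; "None" and
  "Decline to answer" map to all-false.  The lexicon is data, editable.
- **Total sleep missed** = (sleep latency + wake after sleep onset + time
  in bed after waking) in hours.
- **Two-process predicted lapses**: homeostatic pressure S rises toward
  `s_upper` with time constant τ_wake = 18.2 h during wake and decays
  toward `s_lower` with τ_sleep = 4.2 h during sleep — classical
  constants, all overridable; the trajectory uses exact piecewise
  exponential segments (no ODE solver), initialized at S = 0.5 one
  standard 16-h wake block before the first reported bedtime.  The
  circadian process C is a 24-h cosine plus a second harmonic (relative
  amplitudes 1.0/0.3, acrophase 16.8 h local).  Predicted lapses =
  max(0, 2 + 15·(S − C)), an affine map chosen to span a plausible 0–18
  lapse range for a 3-minute test.  The covariate is used *relatively* by
  the models; its absolute calibration is explicitly out of scope.
  Individuals with no sleep data receive the cohort mean
  (provenance `imputed-mean`).
- **Lagged outcome**: the participant's previous observed score; a first
  observation takes the participant's pre-flight mean when supplied, else
  the cohort mean.

## Models

**LME.** y_it = β₀ + X_itβ + b_i + ε_it with random intercepts and AR(1)
residual correlation ρ^|j−k| indexed by within-person observation order
(not calendar gaps — the continuous-time variant is a possible extension).
Fit by REML (ML available): β is profiled out by GLS at each variance
evaluation and Nelder-Mead optimizes (log σ_b, atanh ρ, log σ); σ is the
*marginal* residual SD.  SEs come from (XᵀV⁻¹X)⁻¹; random intercepts are
BLUPs; unseen participants predict at b = 0 (the group average).  Designs
are rank-checked on standardized columns; collinear covariates raise by
default, or are dropped with a log entry when `drop_collinear=True` (used
inside resampling loops where rare binary flags can go constant).

**Random forest.** scikit-learn regression forest, seeded; defaults
n_trees = 500, mtry = ⌊p/3⌋, min leaf 5 (regression conventions — the
hyperparameters are configuration, and the cross-validation experiments
use smaller forests, noted below).  Out-of-bag R² is recorded.

**FCM.** y_ij = β₀ + Σ_p f_p(X_ij⁽ᵖ⁾, t_ij) + b_i(t_ij) + ε_ij with t the
mission fraction ∈ [0,1].  Each f_p is a tensor-product cubic B-spline
surface (5 × 5 basis, uniform interior knots over the training range,
second-order difference penalties in both directions).  The penalty null
space contains bilinear surfaces, so linear, time-constant effects are
recovered without shrinkage; term columns are mean-centered for
identifiability against the intercept, and a small ridge
(10⁻⁷·tr(ZᵀZ)/m) guards the remaining null-space overlap.  Covariates
with < 6 distinct values automatically get a varying-coefficient form
x·g(t) (5 basis functions); per-covariate overrides allow
tensor/varying/linear.  Random curves b_i(t) are per-participant 5-basis
splines under a ridge penalty, so they shrink to zero and vanish for
unseen participants.  The two smoothing parameters (surfaces; random
curves) are selected by GCV over a fixed log-spaced grid (5 × 3).
Evaluation outside the training range clamps to the boundary (constant
extrapolation) — predictions beyond the observed time span revert to the
boundary behaviour, a known limitation.

**Ensemble** = arithmetic mean of the three predictions (weights fixed at
1/3 each; a CV-weighted mode exists but is off by default).  The identity
"ensemble = mean of components" is exact and is verified window-by-window
in the test suite; long multi-model experiments therefore form ensemble
cells by averaging the component runs' predictions instead of refitting a
fourth time.

**Effect heat maps** evaluate the population-level FCM surface on a
(covariate value × mission fraction) grid with all other covariates at
their mean (continuous) or modal/reference (binary) values.

## Forward-chaining validation

For participant i with n_i observations, training length t from
{5, 10, …, 50} and shift k, the model trains on the participant's
observations k…k+t−1 **plus all other participants' complete series** and
predicts observation k+t (and further, up to horizon 7).  The nominal
shift count follows the printed formula N_{i,t} = min(20, n_i − t + 1);
under it the last shifts of a maximal-length window have no test
observation, so `make_windows` emits only windows whose full test horizon
exists and counts the dropped remainder.  (The count function and the
emitted enumeration are tested separately against brute force.)

Aggregation weights people equally: MSE(i,t) averages squared test error
over shifts, MSE(t) averages MSE(i,t) over participants *unweighted*, and
MSE_overall averages MSE(t) over the t grid.  MAE(i,t) is the median
absolute error over shifts (robust to outcome spikes).  Training error
follows the same nesting but also sums over the t window observations and
is squared by default; `literal_train=True` reproduces the unsquared
variant.  RMSE(t)/sd(y) standardizes by the outcome SD over test cells.
The fixed participant-count divisor in the source formulas is generalized
to "participants contributing at that t", which coincides when all do.
Failed window fits are excluded and counted, never zero-filled (zero
filling would bias MSE downward).

Chained individualized prediction refits on all of a participant's prior
data plus everyone else's full series at each observation; uncertainty
bands are the IQR over bootstrap refits that resample the *other*
participants' entire series with replacement (the target's prior data
enters each resample exactly once; duplicated participants are relabelled
so they remain distinct grouping units).

## Variable importance

%IncMSE is the percent increase in aggregate out-of-bag MSE when one
covariate is permuted, computed on a purpose-built bagged ensemble of
regression trees with explicit bootstrap/OOB bookkeeping; node purity is
the summed impurity (variance) decrease from splits on the variable.  The
Top-10 Rate repeats the ranking on 100 Monte-Carlo row subsamples (50%,
without replacement by default; with-replacement and participant-
stratified modes exist) and reports how often each variable lands in the
top 10 by %IncMSE.  Selection sorts by rate, then mean %IncMSE, then name
— fully deterministic.

## Synthetic cohort generator

The generator emulates the study conditions: 24 participants, 160-day
missions, tests twice per day every 4th day (morning ~07:30, evening
~21:00 UTC, ±0.6 h), ~16% in-flight non-adherence, demographics matching
the published cohort summary (age 48.2 ± 4.8, 79% male, pre-flight OPS
0.95 ± 0.02).  Outcome: β₀ = −33 (the published cohort mean) plus
centered covariate effects, person intercepts (σ = 6), AR(1) errors
(ρ = 0.4, innovation σ = 6) and rare one-sided spikes — additive positive
exponential shifts (worse performance), default probability 0.02 and mean
15; the real spike rate/magnitude is unpublished, so these are free
parameters, not calibrated claims.  `truth_betas` keys may be products
(`a*b` of centered factors), enabling quadratic and interaction
components; `time_varying_betas` modulate a coefficient by sin(2πt).
Environment streams: daily radiation with a slow seasonal swing; 10-minute
temperature per module, CO₂ and O₂ with diurnal sinusoids plus AR noise;
acoustic dosimeter sessions of 24 h at 1-minute cadence roughly every
other month per module — so noise is structurally unobserved at almost all
test times, as in flight.  Everything is driven by one seed through
separate child streams; identical configs are byte-identical.

What the generator does **not** emulate: radiation physics or atmospheric
dynamics (the curves are phenomenological sinusoids), EVAs and schedule
shifts, learning/aging trends, non-stationary missingness, or any coupling
between environment and behaviour beyond the specified linear /
time-varying / product effects.  Passing tests therefore demonstrate that
the pipeline's algebra, leakage control and estimators behave as designed
under known truth — not that the models would achieve any particular
accuracy on flight data.

## Problem sizes and numerical choices in the test experiments

- LME recovery: 50 cohorts of 24 × ~64 observations (≈1,536 rows each);
  coverage of each β within 2 SE demanded in ≥90% of replicates.
- Time-varying recovery: 8 × 50 observations per cohort, effect
  amplitude 8·sin(2πt) on temperature; the holdout interleaves every 4th
  observation so the FCM is evaluated at interior times (a terminal-block
  split would measure extrapolation past the spline boundary instead of
  representation).
- Ensemble advantage: mixed truth with linear, interaction
  (temperature×CO₂) and time-varying components scaled by variance
  budgeting to ≈2.5–3 outcome-SD units each, so no single model dominates
  by construction; 20 cohorts of 4 × 22 observations, t-grid {5, 15, 25},
  8 shifts, 60-tree forests.
- Importance: 100 draws × 100 trees on 400 rows with one strong signal
  among 15 noise covariates; the null band check bounds |%IncMSE| by 10
  under independence.
- The full-pipeline CLI run and the acceptance script use an 8-participant,
  64-day cohort with t-grid {5, 10, 15, 20}, 6 shifts and 100-tree
  forests.

Tolerances follow the quantity's structure: exact identities (ensemble
mean, aggregation formulas, OPS/LRM-50 arithmetic) are checked to machine
precision; closed-form dynamics (two-process limits) to 10⁻⁶ against an
independent RK4 integrator; stochastic recoveries use coverage bands or
majority-of-replicates criteria with all seeds frozen.

## Known limitations

- The AR(1) index is observation order; long calendar gaps carry the same
  correlation as adjacent days.
- The FCM's additive surfaces cannot represent covariate×covariate
  interactions (by design — that is the forest's role in the ensemble),
  and extrapolation beyond the training time range is constant.
- LRM-50 values are relative to whichever reference table is supplied;
  the bundled table is synthetic.
- The medication lexicon is keyword matching, not named-entity
  recognition; misspellings fall through (logged).
- The composite PCA uses pairwise-complete correlations, which need not be
  positive semidefinite in pathological missingness patterns; eigenvalues
  are clipped at zero for the variance share.
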
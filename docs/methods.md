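# Methods

## Data model

One record per woman: an ordered series of vaginal exams (hours since
admission, integer cervical dilatation 0-10 cm), the exactly recorded time
of full dilatation, and the covariates the selection chain needs (parity
group 0/1/2+, gestational age, presentation, onset type, prior uterine
scar, mode of birth, adverse-outcome and severe-malformation flags,
oxytocin augmentation). Modelled dilatation levels are 2,3,...,8,10: 9 cm
is never documented in this kind of cohort, so 8 cm advances directly to
full dilatation.

Sample selection keeps term (37+0 to 41+6 weeks, both ends inclusive),
vertex, spontaneous-onset labours admitted at <= 6 cm that ended in vaginal
birth with no severe adverse outcome or malformation and at least two
dilatation assessments (detecting 10 cm counts as an assessment — a single
data point cannot define a progression pattern). A record failing several
criteria is attributed to the first failing one in the order above; the
included set itself is order-invariant (tested). An optional outlier hook
(maximum plausible dilatation rate, monotonicity) exists in the reader but
is disabled by default because no threshold is defined for it.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are not tuning
knobs.

* **Sojourn truth.** Per parity group, each 1-cm sojourn (and 8->10 cm) is
  an independent log-normal whose (mu, sigma) invert the published
  survival median/95th-percentile pair: mu = ln p50,
  sigma = (ln p95 - ln p50)/1.645. The 2->3 cm step has no published row
  and reuses the 3->4 cm parameters. Independence across transitions is
  the simplest structure consistent with every fitted model; no
  correlation structure is published.
* **Admission.** Admission dilatation is drawn from the published
  per-parity stratum counts at 3-6 cm, the remainder (women arriving
  before 3 cm) pooled at 2 cm. Admission is placed at the instant the
  latent path reaches that dilatation, so the reaching time of the
  admission level is exactly 0 on the observation clock. This is an
  idealisation (a real woman is admitted partway through a sojourn); it
  keeps the sojourn and cumulative estimands unbiased with respect to the
  calibration and matches the convention that women admitted at d
  contribute exact-origin data for the d -> d+1 transition.
* **Exam schedule.** No schedule is published, only the per-woman exam
  count summary (median 3, 10th percentile 2). Gaps are truncated normal,
  mean 4.75 h (SD 1.5, minimum 1.5) while the last observed dilatation is
  below 7 cm and mean 1.0 h (SD 0.4, minimum 0.3) from 7 cm — labour
  monitoring intensifies in advanced labour. This reproduces median 3 and
  10th percentile 2 in every parity group; the simulated 90th percentile
  (6-7) is heavier than the published 5, the price of combining a sparse
  median with log-normal duration tails. Because the next exam time
  depends only on the *observed* history, the schedule is ignorable for
  every likelihood fitted here.
* **Oxytocin.** Flags are Bernoulli at the published rates, independent of
  the latent path by default. With `couple_augmentation=True` women in the
  slower half of latent 3->5 cm progress are flagged at 1.5x the marginal
  rate (and the faster half at 0.5x), emulating the clinical selection of
  slow labours for augmentation that drives the sensitivity analysis.
* **Planted exclusions.** Records violating exactly one selection
  criterion are added at configured rates (defaults of order 0.4-6% per
  criterion; the source flow chart prints no usable counts, so these are
  the package's own realistic choices). The planting bookkeeping is the
  oracle for the filter tests.

What the generator does **not** emulate: measurement error and
inter-observer variation in dilatation assessment, rounding of exam times,
within-woman correlation of sojourns, covariate effects on speed, and
second-stage events beyond the full-dilatation timestamp. Passing tests
therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to those real-data features.

## Interval-censored survival analysis

Reaching brackets: for each level d above admission, the reaching time lies
in (last exam below d, first exam at or >= d]; the admission level is exact
at 0 and full dilatation exact at its recorded time.

*Cumulative durations* (admission to level d) use these brackets directly —
the origin is exact, so this is genuine interval censoring and the MLE is
consistent.

*Sojourns* combine two brackets. The exposed `sojourn_data` op forms the
conservative single interval [max(0, L'-U), U'-L], which surely contains
the truth but badly attenuates transitions faster than the exam spacing
(fitted parity-0 7->8 cm median 0.03 h against a truth of 0.25 h at full
cohort size). The table pipeline therefore uses the pair-bracket
likelihood: the unknown origin u is integrated uniformly over its own
bracket,

  P(datum) = (1/(U-L)) * integral_L^U [F(U'-u) - F(max(L'-u, 0))] du,

with 16-point Gauss-Legendre nodes, degenerating to the standard censored
(or exact) terms when a bracket has zero width. This is strictly tighter
and removes most of the attenuation for transitions at or above the exam
timescale.

Optimisation is Nelder-Mead over (mu, ln sigma), multistart from
log-midpoint moments, objective tolerance 1e-8. With only exact data the
estimate equals the closed-form mean/SD of log durations (tested), and on
genuinely interval-censored data it matches lifelines'
`LogNormalFitter.fit_interval_censoring` (tested).

**Identifiability limit.** When a sojourn is much shorter than the exam
spacing, ~85% of brackets are left-censored at one gap and the likelihood
has a (mu, sigma) ridge: no estimator can pin both parameters. Parameter
recovery is therefore validated under an inspection design spaced at half
each transition's median (all parity-0 transitions recover mu and sigma
within +-0.1 at n = 2,000), while under the sparse study-condition
schedule the end-to-end sojourn medians recover the slow early transitions
(nulliparous 3->4 and 4->5 cm within ~10-20%) and attenuate the sub-hour
ones downward — never upward (tested). The same asymmetry is visible in
the published tables, where the survival column sits well below the Markov
column for exactly those fast transitions. Cumulative durations to full
dilatation, which carry the clinical thresholds, recover their true
medians within a few percent at every admission level (tested at 15%
tolerance including Monte-Carlo noise).

The 95th-percentile staircase applies a running maximum across target
levels so the emitted threshold line is a valid nondecreasing step
function even under estimation noise.

## Multistate Markov model

Time-homogeneous progressive chain per parity group; one free intensity
per transient state, fitted by L-BFGS-B over log-rates. P(t) entries are
evaluated through the eigendecomposition of the triangular Q (exact and
fast for distinct rates), falling back to `scipy.linalg.expm` per distinct
time gap whenever two rates come within 1e-5 relative of each other.
Exams enter as panel snapshots ln P(dt)[r,s]; the recorded full-dilatation
time enters as an exact transition density [P(dt) Q][r, 10]. The delivery
rate (10 cm -> D) is never informed by a cohort CSV (no delivery
timestamps) and is flagged non-identifiable and held at its initial value;
it does not affect any reported table. Standard errors come from the
numerical Hessian of the log-likelihood.

Percentile tables are produced, as published practice dictates, by
simulating the fitted chain on a fixed 5-minute grid (0.0833 h, exposed as
a flag): one-step probabilities P(step), states skipped within a step get
zero sojourn, and the smallest positive reportable time is one step —
reproducing the characteristic 0.08-hour floor of grid-simulated 5th
percentiles. Sojourn quantiles agree with the analytic exponential
quantiles -ln(1-p)/q within one grid step (tested at n = 50,000); the
analytic quantiles are available directly on `IntensityMatrix` as a
cross-check. Cumulative tables are empirical first-passage percentiles per
admission state; the average labour curve is the mean state value at each
reversed time tau before reaching 10 cm, over women still in labour at
tau, anchored at exactly 10 cm at tau = 0.

Because the chain's exponential sojourns cannot match log-normal truth in
both tails, Markov and survival medians are compared only as a sanity
band: within 30% for mid-labour transitions on a densely examined cohort
(tested), looser on the sparse default schedule where the two estimators'
biases point in opposite directions for fast transitions.

## Logistic growth mixed model

Fitted on the signed reverse-time axis (exam time minus full-dilatation
time, <= 0); the reflected positive axis of published displays is
presentation only. The published model equation carries no residual term;
a Gaussian residual sigma_eps is added because no likelihood exists
without one. The marginal likelihood integrates the random inflection
shift per woman by adaptive Gauss-Hermite quadrature: a grid-initialised,
ascent-guarded Newton search finds each woman's mode and curvature, women
whose observations sit entirely on the 10-cm plateau (one-sidedly
identified b) are widened to the prior scale, and one moment-matched
re-centring pass follows. 21 nodes by default; the residual truncation
error against a 41-node evaluation is O(1e-3) in total log-likelihood
(dominated by plateau-only women) — small relative to the likelihood but
not reducible by re-centring alone.

The outer optimisation is Nelder-Mead over (beta0, beta1, beta2,
ln sigma_b, ln sigma_eps), multistart (pooled-NLS-based start plus two
anchored heuristics) because the surface has a near-linear ridge: when the
observed range contains no inflection, (beta1, beta2) trade off almost
freely. On step-function cohort data the fitted parameters ride that ridge
and sigma_b typically collapses to its boundary (reported, not clipped) —
but the population curve inside the observed range is stable, which is why
the analysis reports curve values at fixed reversed times rather than raw
parameters, and flags inflection points falling outside the observed
range. On data generated from the model itself all five parameters are
recovered within 3 standard errors at n = 500 (tested). With sigma_b = 0
the fit reduces to pooled nonlinear least squares (tested against
`scipy.optimize.curve_fit`).

The alert-line comparison clocks a 1 cm/hour line from each woman's first
exam at or above 4 cm and counts women with any later exam strictly below
it.

## Orchestration and reporting

`run_full_analysis` chains selection -> per-parity survival + Markov +
logistic -> optional re-run without augmented labours -> signed
difference-of-medians tables (all women minus women without oxytocin;
signs are preserved, not absolute values). All tables are tidy DataFrames
tagged with method, parity and population; times are decimal hours printed
to 2 decimals. Identical configuration and seed give byte-identical
outputs (tested). Analysis sizes used by the drivers and the acceptance
script: the full published stratum sizes for fitting; 20,000-100,000
simulated trajectories for Markov tables (the acceptance script uses
100,000).

## Known limitations

* Marginal per-transition survival fits on sparse panels attenuate
  sub-hour sojourns (quantified above); a full path likelihood or the
  multistate model is the remedy, which is precisely why both families
  are run.
* The Markov model's exponential sojourns understate tail heaviness
  relative to log-normal truth; its 5th/95th percentiles are
  grid-resolution-limited by construction.
* The logistic curve parameters are weakly identified when the inflection
  lies outside the observed range; only the curve inside the range should
  be interpreted.
* The generator's independence and exact-anchoring idealisations mean
  real-data biases from measurement error and informative admission
  timing are out of scope.
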
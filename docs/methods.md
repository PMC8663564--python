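# Methods

## Data model

The unit of analysis is one participant's chronologically ordered series for
one test — or one participant-hand for the dexterity tests, which alternate
hands. Records are indexed 1..n by timestamp (ties broken by input row
order, so same-day repetitions index deterministically), and carry two time
axes: `t_rep = repetition − 1` and `t_weeks = (timestamp − first)/7 days`.
Anchoring the model time at the first test makes the bounded-growth
intercept equal the expected first-trial score.

Raw exports are long-format CSV with one row per test and metric. Only each
test's primary metric is kept; the default column and metric names match the
public export and every name is overridable, since export schemas drift.
Date-only timestamps are imputed at 12:00 so week arithmetic cannot flip
across day boundaries. Hand labels are normalized case-insensitively to
left/right; anything else on a hand-grouped test drops the record with a
warning. Malformed rows are counted, logged and skipped — a single bad row
must not kill a cohort load.

The e-SDMT dexterity correction divides the 60-second symbol-digit score by
the 15-second digit-tapping "baseline" step recorded with the same
timestamp. Records with a missing or zero denominator are dropped (counted),
and the corrected cohort refuses a second application: the ratio is
dimensionless and dividing it again would be meaningless.

## Selection and characteristics

Units enter the analysis with ≥ 5 repetitions and ≥ 5 weeks between first
and last repetition (10/10 in the stricter sensitivity cells). "5 weeks" is
implemented as elapsed time ≥ 35 × 24 h; calendar-day counting would
reclassify borderline units and the convention is therefore recorded in the
cohort provenance. Characteristics tables report the cohort-level median
(IQR; range) of per-unit statistics — repetition count, median and IQR of
consecutive intertest intervals, weeks of follow-up — using the
linear-interpolation quantile convention throughout; quantile conventions
move these numbers and so are fixed package-wide. Ages are summarised over
participants, not hands.

## Summary effects

Percent improvements (first→fifth, fifth→last, first→last) are computed per
unit and then averaged — the mean of per-unit ratios, not the ratio of
means; the ratio-of-means variant is also emitted for transparency. Units
with a zero first or fifth score are excluded from percent computations
(flagged and counted). Confidence intervals are two-sided t intervals on
n−1 df; whether bootstrap intervals would be preferable is moot at these
cohort sizes. Signs are never flipped for lower-is-better metrics: an
improvement on sway path prints as a negative percent change.

The long-term practice indicator regresses (last − fifth) on age, first
score, fifth score and ln(repetitions) by OLS. The natural log is a scale
choice only; repetition counts are strongly right-skewed, which is the
reason for the transform. A rank-deficient design raises an error naming
the columns rather than silently dropping one.

## Short-term learning (quantile panel)

For each test the first five trials of all selected units are pooled and a
straight line in repetition number is fitted at τ ∈ {.05, .25, .50, .75,
.95}. The line is parameterized as `y = β0 + β1(t − 1)`, so β0 is the
τ-quantile at the first repetition — baseline performance of that percentile
group — and β1 the learning rate in metric units per repetition.

Point estimates minimize the check (pinball) loss exactly via the standard
linear-programming formulation (HiGHS). Because the optimum can be a face
rather than a vertex, two further LPs over the optimal face select the
lexicographically smallest (intercept, slope), making fits reproducible to
solver tolerance. The pairwise-line enumeration property (some optimal line
passes through two data points) is used as a brute-force oracle in the
tests, never in the fit itself.

Repeated measures within a unit are dependent, so standard errors and the
joint 5×5 slope covariance come from a cluster bootstrap that resamples
units, not rows (default 1000 replicates; below 100 a warning is issued).
Refitting an exact LP per replicate per τ would dominate the runtime, so
bootstrap replicates are refitted with a vectorised iteratively-reweighted
least-squares smoother of the same loss (all replicates solved
simultaneously as weighted problems; ε-regularised weights, initialised at
the exact fit). The point estimates themselves always come from the exact
LP. Degenerate replicates (no spread in repetition number) are redrawn and
counted. Slope p-values use the normal approximation and are
Bonferroni-adjusted for the family of five slopes; intercepts are reported
with unadjusted CIs, since learning-rate inference is the target of the
multiplicity control.

Slope homogeneity is tested with a Wald statistic on the four successive
slope differences, W = (Dβ̂)ᵀ(DV̂Dᵀ)⁻¹(Dβ̂) ~ χ²(4) under equality — an
ANOVA-type test implemented from its definition because the joint
covariance comes from the bootstrap. Under a common true slope (200 units,
5 trials) the simulated rejection rate at α = .05 is ~2–4% with 150–400
bootstrap replicates, i.e. slightly conservative, which is the safe side
for a screening test.

## Learning-curve models

Four models of score versus time are compared on the selected cohort of a
flagged test; time is repetitions since first test in the main analysis and
weeks since first test in sensitivity cells S1/S3.

* **Linear mixed model** (df 4 = 2 fixed + intercept variance + residual)
  and **quadratic mixed model** (df 5), both ML fits with a random
  intercept per unit (statsmodels MixedLM). Data lying exactly on one
  population line/parabola short-circuit to the OLS solution, since a zero
  residual variance is outside the mixed-model optimizer's domain.
* **Penalized regression spline**: cubic B-splines on 10 equally spaced
  basis functions with a second-difference coefficient penalty, whose null
  space is exactly the straight line (so linear data yields edf ≈ 2). By
  default the additive model also contains a ridge-penalized intercept per
  unit — the random-effect representation of the grouping structure — since
  the mixed models it is compared against all account for within-unit
  correlation; a pure population smoother is available via
  `unit_effects=False`. Both penalties are selected by GCV on a log grid;
  exact GCV ties (zero-noise data) resolve to the smoothest fit. The
  effective df is the trace of the influence matrix, computed blockwise
  through the Schur complement.
* **Bounded-growth mixed model** (df 6 = 3 fixed + 2 variances + residual):
  `y = boundary + (y0 − boundary)e^(−ct)` with independent Gaussian random
  effects on y0 and boundary. Conditional on c the model is linear in the
  random effects, so the marginal likelihood is evaluated *exactly* via the
  Woodbury identity on rank-2 per-unit covariance updates; fixed effects
  (GLS) and the residual variance are profiled in closed form and the
  optimizer works on (log c, log σ²_y0/σ², log σ²_b/σ²). Initialization
  profiles c on a 50-point log grid; L-BFGS-B is polished by a
  derivative-free pass and the exit gradient is checked (except at
  perfect-interpolation optima, where σ²→0 makes the likelihood unbounded
  and the check meaningless). The covariance of the two random effects is
  fixed at zero to keep the 6-df accounting. With both variance ratios
  pinned at zero the fit reduces exactly to pooled nonlinear least squares,
  which is verified against a brute-force grid-search oracle to 1e−6
  relative, and the full fit is cross-checked against R's `nlme`
  (a linearization-based estimator of the same model): the exact marginal
  likelihood at our optimum is never below nlme's solution.

  Identifiability: when the likelihood is flat in c (improvement within ~2
  log-likelihood units of the search bounds, or c at a bound), the boundary
  is not identified — flat or instantaneous learning — and the fit raises an
  error advising the linear model instead of returning a meaningless
  plateau.

Model fit is compared by the root mean squared **conditional** residual
(unit-level BLUPs included) for all mixed models, consistent with the
spline's fitted values including unit intercepts; whether a marginal RMSE
would be preferable is a convention choice and this one makes the four
models comparable on fit-to-observations. Ties in RMSE break toward fewest
df.

Fixed-effect CIs are Wald intervals from the GLS covariance; the CI for c
comes from the profile-likelihood curvature in log c. BLUPs use the
standard conditional-mean formula and give per-unit (y0ᵢ, boundaryᵢ).

### Practice metrics

From a converged bounded-growth fit: practice points `t_p = −ln(1−p)/c`
(p = 0.5 and 0.9 by default; t90/t50 = ln10/ln2 ≈ 3.32 identically), the
tangent slope `m(t) = c(boundary − y0)e^(−ct)`, and the boundary improvement
over baseline in percent, reported two ways: the mean of per-unit BLUP
ratios 100(boundaryᵢ − y0ᵢ)/y0ᵢ with a t-based CI (subject-level averaging,
which yields narrow CIs), and the fixed-effect ratio 100(μ_b − μ_y0)/μ_y0
with a delta-method CI. Under independent random effects the subject-level
mean exceeds the fixed-effect ratio (Jensen effect of the random baseline in
the denominator); on real data, where baseline and plateau are positively
coupled, the two agree more closely. Raw and integer-rounded practice
points are both reported because rounded repetition counts are what a study
protocol can act on.

## Synthetic cohorts

The generator emulates the study conditions: per-unit bounded-growth
trajectories with Gaussian baseline/boundary and additive Gaussian noise on
the repetition axis; repetition counts from a lognormal law (rounded up,
truncated at the observed maximum) whose (μ, σ) are least-squares calibrated
to the target median and IQR; intertest intervals lognormal in days and
floored at the app-enforced minimum (7 d cognition, 2 d per hand dexterity,
1 d mobility); an age covariate coupled to adherence through a Gaussian
copula at the reported correlation (~0.2); two interleaved units per
participant for hand-grouped tests. Per-test presets calibrate trajectory
parameters to the reported bounded-growth estimates (e.g. cognition:
baseline 41.0, boundary 57.7, c = ln2/11, residual SD 3.3; baseline SD 10
from the spread of the percentile-group intercepts) and schedules to the
reported adherence tables; mobility tests, which showed no long-term
practice, are emulated as flat or fast-saturating curves. One root seed
spawns an independent child stream per unit, so enlarging a cohort never
reshuffles existing units.

What the generator does **not** emulate: the mostly-dropout population
below the selection threshold (presets describe the *selected* cohort, so
selection fractions on synthetic cohorts are high by construction),
non-Gaussian score distributions (the sway-path metric is strongly
right-skewed in reality), correlation between baseline and plateau,
relapses or disease progression, and informative dropout. Passing tests on
these cohorts therefore demonstrate correctness of the estimators under the
stated model, not robustness to every feature of real exports.

## Pipeline

Per test: selection report → characteristics → summary effects → confounder
regression and correlation panel → quantile panel with the slope-equality
test → and, only for tests flagged with long-term practice, the four-model
curve analysis with practice metrics. The flag requires both stated
indicators: the 95% CI of the mean fifth-to-last percent improvement
excludes zero, and the ln(repetitions) coefficient is significant at .05
with the sign matching the improvement direction. Stage failures are
captured per test and never abort the remaining tests. Output is a
JSON bundle (plus TSV tables) stamped with package version, configuration
and seed; identical configuration and seed give byte-identical output. The
sensitivity grid runs the four cells {5/5, 10/10} × {repetition, weeks} and
tabulates fifth-to-last improvements and boundary improvements side by
side; its main cell is by construction identical to the main analysis.

## Problem sizes and numerics

Simulation-based tests run at 150–300 units with 100–500 bootstrap
replicates and 5–10 seeds per claim; the acceptance script uses 262-unit
study-scale cohorts, 10-seed recovery/ordering studies and a 100-simulation
null calibration. Convergence tolerances: outer optimizer ftol 1e−12 with a
relative gradient check at 1e−3; GCV grids span 1e−7–1e9 around a
trace-matched scale (40 × 30 points); quantile LP tie-breaking slack 1e−9
relative. Degenerate inputs (zero variance, zero noise, constant series,
flat curves) are handled by explicit guards rather than optimizer luck, as
described above.
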
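# Methods

`circavol` implements a complete analysis chain for two-arm wrist-actigraphy
trials in mood-disorder populations: non-parametric circadian rest-activity
metrics from epoch-level acceleration data, a hierarchical Bayesian filter
that decomposes each daily series into mean, volatility and noise, and
linear mixed models for group x phase treatment contrasts. A synthetic-data
module generates every input the chain needs, so the whole pipeline is
testable end to end without any recorded data.

## Non-parametric rest-activity metrics

Raw triaxial samples (g-units at a fixed rate) are summarised per epoch as
the signal magnitude vector, SVM = sum |sqrt(x^2+y^2+z^2) - g|: the
within-epoch sum of absolute deviations of the Euclidean acceleration norm
from gravity. A recording day is excluded when more than 3 h of non-wear is
flagged (exactly 3 h is still valid); non-wear flags are taken from input,
with an explicitly non-canonical stationarity heuristic (rolling SD below
threshold for >= 30 min) available as a fallback.

Daily summaries are the classic non-parametric pair:

* **M10** - total activity in the most active 10-h window, searched at epoch
  resolution over 00:00-24:00 of the day; onset = window start hour.
* **L5** - total activity in the least active 5-h window, searched noon to
  noon of the following day, with onset reported in hours after the focal
  midnight (so typical values are ~25 h). The generator therefore simulates
  36-h days (midnight through next noon) so this search never truncates.

Both searches step one epoch and break ties toward the earliest start, which
makes them deterministic and exactly reproducible by brute-force
enumeration; window sums use direct per-window summation rather than a
cumulative-sum trick so the equality with enumeration is bit-exact.

Period-level rhythmicity uses clock-hour bins (epoch values summed per
hour, partial trailing hours dropped):

* relative amplitude RA = (M10 - L5)/(M10 + L5), computed from period-mean
  amounts first rescaled to per-hour means (a raw 10-h sum against a raw
  5-h sum would inflate RA);
* interdaily stability IS = [N sum_h (xbar_h - xbar)^2] / [24 sum_i (x_i -
  xbar)^2], the variance of the 24 hour-of-day means relative to total
  variance (1 for a perfectly repeated profile, ~1/D for D days of noise);
* intradaily variability IV = [sum (x_i - x_{i-1})^2/(N-1)] / [sum (x_i -
  xbar)^2/N], the normalised mean squared successive difference (~2 for
  white noise, near 0 for a smooth profile).

IS and IV are 0/0 on constant input and raise an explicit
`UndefinedMetricError` rather than returning 0; period summaries with fewer
than 2 valid days record missing values instead of raising.

## The Bayesian volatility/noise filter

Each daily series (PA, NA, M10 level, L5 level, and the two onsets) is
modelled, after a bounded logit transform, as a Gaussian observation around
a drifting latent mean:

    log vmu_t = log vmu_{t-1} + Normal(0, kmu)
    log SD_t  = log SD_{t-1}  + Normal(0, vSD)
    mu_t      = mu_{t-1}      + Normal(0, exp(log vmu_t))
    y_t       ~ Normal(mu_t, exp(log SD_t))

*Volatility* (vmu) is the step size of persistent drift in the mean;
*noise* (SD) is transient scatter that does not carry forward. The bounded
transform `logit((raw - min)/(max - min) * 0.8 + 0.1)` maps the observed
range onto an unbounded scale with finite endpoints (min -> ln(1/9), max ->
ln 9). Transform bounds are per-series observed min/max by default;
fixed bounds (e.g. the 5-25 range of a PANAS subscale sum) are available
as an option. A series with a degenerate range, or fewer than two
observations, is marked unavailable rather than filtered.

### Numerical scheme

Inference is a dense grid filter. The joint posterior over (mu, log vmu,
log SD) is carried as a probability mass array with one slice per
(kmu, vSD) candidate pair, mixed by Bayesian model averaging (the candidate
weights are the accumulated marginal evidences). Each day applies:

* **predict** - diffusion through discretized transition kernels: log vmu
  with its kmu candidate, log SD with its vSD candidate, then mu with step
  SD exp(log vmu) conditional on the *new* log-volatility cell, matching
  the generative ordering. Kernels are Gaussian CDF differences over cell
  edges with the outer cells extended to +-infinity, so mass is conserved
  exactly; the share that would have left the nominal bounds is logged as
  a leakage diagnostic when it exceeds 1%.
* **update** (observed days only) - multiplication by the Gaussian
  likelihood *integrated over each mu cell* (CDF difference across the
  finite cell edges). Point-evaluated densities are not used: with a
  log SD grid reaching very small noise levels, a point-evaluated
  likelihood turns small-noise cells into grid-alignment lotteries and
  makes the posterior mean sensitive to the grid; the cell integral
  removes that aliasing. Development verified this directly: with point
  evaluation, doubling the grid moved posterior-mean trajectories by tens
  of percent; with cell integration the change is a few percent and
  shrinks with resolution.

Missing days get predict only, so the posterior spread of the mean grows
monotonically through every gap - the filter still reports estimates for
unobserved days, with honestly larger uncertainty.

Point estimates are expectations of the marginalized posterior, reported in
the estimation space (mu in transformed units; volatility and noise in log
units). Back-transforms to raw units are provided for convenience but the
downstream models consume the estimation-space values.

Defaults: 40 grid points per dynamic dimension; mu bounds are the
transformed interval [logit(0.05), logit(0.95)] widened by 20%; log vmu and
log SD span [-6, 1]; 5x5 (kmu, vSD) candidates log-spaced in [1e-3, 1];
uniform priors over all grids. A grid-refinement diagnostic (`--grid-check`)
doubles every grid size on a reference simulation and reports the RMS
change of the posterior-mean trajectory. On coarse 8^3 grids the filter
agrees with an independently coded dense enumeration of the same
discretized model to better than 1e-6 in every reported expectation, which
pins the implementation to the model definition above.

## Trial analysis

Days are binned into run-in (day -14..0) and weeks 1-4 (days 1-7, 8-14,
15-21, 22-28); later days are excluded. The long analysis table has one row
per participant-day-activity-type-measure. Level and onset rows exist only
for valid observed days; volatility and noise rows cover every filter day,
because the filter estimates them through gaps - so variability analyses
have more data points than level analyses. Daily log-PA on missing days is
imputed from the PA track's back-transformed posterior mean; PA volatility
comes from the same track.

Three REML mixed-model families (statsmodels `MixedLM`):

* activity (levels or onsets):
  `value ~ arm * activity_type * phase + log_pa + pa_volatility + age +
  sex + season + (1 + activity_type | participant)`;
* variability: the same with an additional `variability_type`
  (volatility | noise) factor, fitted separately for level and onset
  tracks;
* rhythmicity (RA / IS / IV per period): `value ~ arm * phase + covariates
  + (1 | participant)`.

Reference levels are the placebo arm and the run-in phase, so the
`arm x phase` coefficients are the weekly treatment contrasts at the
reference activity type; releveling (refitting with the other reference)
yields the remaining contrasts. An optional weekday/weekend covariate is
available behind a flag.

### Inference conventions

Because M10 and L5 (and volatility and noise) share one model, their
residual scales differ by orders of magnitude, and the pooled residual
variance of a standard mixed model understates the reference-level contrast
standard errors - in null simulations this nearly tripled the nominal 5%
rejection rate. Fixed-effect inference therefore defaults to a
participant-clustered sandwich covariance around the GLS estimates
(consistent under residual heteroscedasticity and under within-person
day-to-day correlation that the random effects do not capture), with a t
reference on (participants - 1) degrees of freedom. Under the null
generator this restores the empirical type-I rate to ~0.05. The naive
pooled-variance convention remains available (`p_method='residual'`).
Coefficients B stay in raw units. The standardized effect size is
d = 2t/sqrt(df_residual); p-values are reported unadjusted, with no
correction across the four post-randomization weeks, and every results file
carries both convention strings.

Within-subject correlations between daily variables are estimated as the
fixed slope between grand-z-scored variables with a per-participant random
intercept - a proxy for pooled within-person Pearson r. Change-score
associations (week-4 mean minus run-in mean per participant) use partial
correlation given covariates (pingouin), cross-checked in tests against a
residual-residual computation.

## The synthetic trial generator

`simulate_trial` works at daily resolution: per participant and measure, a
truncated-normal baseline plus a latent random walk plus day-to-day
Gaussian noise, clipped to the measure's physical range (PANAS sums rounded
into 5-25; onsets kept inside their search windows). Defaults describe a
mood-instability cohort on field-typical scales: M10 57.3 (between-person
SD 18.9), L5 3.9 (0.7), M10 onset 12.3 h, L5 onset 25.5 h, PA 10.6, NA
9.7; recording spans day -14..28 (43 days) with i.i.d. missing days at
rate 0.30, giving the realistic median of ~13 missing days per participant.
Day-to-day M10 variation is truncated-normal by default with a log-normal
multiplicative option.

Within-person dynamics set the M10 daily noise to 8 units and the drift
step to 1.5 units/day: sizeable persistent drift is what makes volatility a
meaningful, identifiable quantity in this population, while week-binned
level contrasts remain calibrated because inference is cluster-robust. PA
daily noise (1.4) is chosen so affect's within/between variance split
matches the activity measures', which keeps the standardized mixed-model
slope an unbiased reader of the coupling parameter below.

Treatment effects are week-indexed maps applied to the active arm only:
M10 multiplied by (1 + effect), onset shifted in hours, latent
log-volatility shifted additively. The defaults mirror the direction and
rough size of effects the pipeline targets (M10 -19% to -31%, onset -1.55
to -1.69 h in weeks 3-4, log-volatility +0.23 to +0.45); they are
calibration aids, fully configurable, not ground truth. Note that in the
default worked example the level steps themselves register as extra
volatility, so the recovered volatility contrast exceeds the injected
shift - volatility injections should be studied with level effects off.

PA is coupled to pre-treatment M10 within person: each day's PA deviation
from the participant's baseline is a rho-weighted mix of the scaled M10
deviation and an independent deviation (rho = 0.15 by default), so the
generator's day-level M10-PA correlation equals the stated parameter.

Hourly data for IS/IV are reconstructed per valid day as a square wave
(m10/10 per hour in the 10-h active window at the day's onset, l5/5
elsewhere) plus truncated Gaussian noise (SD 1.5); an IS effect map scales
that noise in the active arm, so a negative value produces a more stable
pattern.

What the generator does *not* emulate: raw 25 Hz accelerometer physics,
non-Gaussian activity bout structure, weekday/weekend routine differences,
informative (non-random) missingness, and dose titration. Passing tests
demonstrate internal consistency of the method chain under the stated
stochastic model, not performance on recorded wrist data.

## Problem sizes used by the test suite and acceptance script

Simulation studies run at desk scale, chosen once: mixed-model calibration
uses 200 null replicates of a 20-per-arm trial (rejections pooled over the
four weekly contrasts) and 60 replicates for power against a -20% M10
effect in weeks 3-4; filter recovery uses 50 step-change series of length
60 on 20-point grids with 3x3 candidates; the filter-vs-enumeration check
uses 20 series of length <= 10 on 8^3 grids; coupling recovery averages 5
replicates of an ~35-participant trial. The acceptance script recomputes
the same quantities at moderately reduced replicate counts and finishes in
a few minutes on one CPU.

## Known limitations

* The filter is a forward pass only; no smoothing, so early-series
  estimates reflect the uniform prior (volatility estimates decline over
  the first days as the posterior tightens - a filter artefact, not a real
  change).
* Grid filters quantize: posterior means inherit an error floor of order
  the cell width; the refinement diagnostic quantifies it.
* Cluster-robust SEs are asymptotic in the number of participants; at very
  small n they can be liberal.
* The filter-estimate tracks fed into the variability models are smooth
  within participant, so their effective information is closer to
  participants than to participant-days; detecting volatility shifts
  needs either large shifts or more participants than level effects do.
* Mixed models assume the activity-type random slope captures
  participant-level heterogeneity; no day-level serial correlation
  structure is modelled beyond it (the sandwich absorbs the consequences
  for inference, not for efficiency).
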
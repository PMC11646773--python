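# Methods

This note documents the models and procedures posturekit implements, the
defaults it ships, the design choices taken where several conventions are in
use, and what the synthetic-data tests do and do not establish about real
recordings.

## Signal conditioning

Force-plate channels are conditioned in a fixed order: mains-hum removal
first, then low-pass filtering. The hum filter folds the record at the mains
period (rate/hum_freq samples), takes the median across periods at every
phase, de-means that waveform (so DC passes), and subtracts it sample-wise.
Because the median is robust, broadband signal riding on the hum barely
perturbs the estimate; the filter affects only the hum frequency and its
harmonics, which is why a pure 50 Hz contaminant drops by >50 dB while
off-harmonic power moves by well under 1 dB. For sampling rates that are not
an integer multiple of the hum frequency the waveform is estimated on a
rounded-period phase grid from the largest whole number of periods and
subtracted by linear phase interpolation. At least three hum periods of data
are required. The hum frequency defaults to 50 Hz (European mains) and is
configurable.

The low-pass stage is a Butterworth filter, order 2 per pass, applied
forward and backward (zero phase). Zero-phase application was chosen because
the target-error metrics are temporal averages of distances and a
phase-lagged COP would bias them; the squared magnitude response puts the
corner gain at 1/2 rather than 1/√2. Cutoffs are 20 Hz for marker channels
and 40 Hz for force channels. Edges are handled by reflective padding of
about three time constants of the corner frequency. Markers receive only the
Butterworth stage; the hum filter applies to force channels.

## COP and target errors

The COP is computed per plate from static moment balance,
COPx = (−My − Fx·z₀)/Fz and COPy = (Mx − Fy·z₀)/Fz in the plate frame, then
transformed to the lab frame (plate origin + yaw) and expressed in mm. The
surface offset z₀ defaults to 0 (plate surface as reference). Samples with
Fz below `min_load` (default 10 N — standard practice to keep the division
stable as the load vanishes, e.g. between beam contacts) are masked invalid
and excluded from every temporal average. During double support the two
single-foot COPs are combined as an unweighted per-sample spatial average by
default; a force-weighted average is available as an option. Where only one
foot carries load, its COP is used directly.

Metrics: the balance-beam error is the mean perpendicular distance from the
COP to the beam centreline segment (beyond the beam ends, distance to the
nearest endpoint); the one-leg-stand error is the mean distance from the
trajectory barycenter (the time-average position over valid samples); the
precision-jump error is the horizontal distance of the big-toe marker from
the target-line segment at the landing instant. The landing is detected as
the first time the vertical force exceeds 20 N and stays above it for 20 ms
(brief spikes are rejected); landings beyond the lateral extent of the
target segment are scored against the nearest endpoint and flagged. Beam
trials interrupted by falls are handled by masking unloaded samples invalid
rather than cropping, so resumed segments concatenate naturally. All three
errors are frame-invariant under rigid lab-frame transformations and are
reported in mm, lower = better.

## Outlier screen and score tables

Motor target errors pass a per-fit screen before model fitting: values
outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] — quartiles by linear interpolation —
are removed, and a warning fires if more than 5% of a fit's data is removed.
The screen is applied per dependent variable and hypothesis dataset;
cognitive and symptom scores are never screened. Changing the quartile
convention moves masks only at boundary ties.

The d2 attention test contributes two scores: concentration capacity
(targets identified minus missed minus falsely marked) and completed targets.
The speed count is operationalized here as targets worked through
(identified + missed); the per-line letters-processed count is retained in
the data model for labs that prefer it. Symptom scales contribute one
arithmetic mean score per child and scale (attention deficit,
hyperactivity); missing items are dropped from the mean with a warning.

## Mixed models

Two designs are pre-registered on the long outcome table. H1 restricts to
intervention-arm subjects at the pre session and tests the condition factor
(ADHD) with Age as an additive covariate. H2 restricts to affected subjects
and tests Time, Skating (intervention arm) and their interaction with Age
and Medication additive. Covariates never interact with factors. Factors are
sum-coded (−1/+1), so each main-effect test refers to the balanced average
over the other factor.

Motor errors (positive, right-skewed, trial-level) use the gamma family with
the canonical inverse link; cognitive and symptom scores use the normal
family with identity link. The random structure is a per-subject intercept
plus a slope on the pre/post contrast, with independent variances (the
intercept–slope correlation is fixed at zero; with two sessions it is weakly
identified and the generator draws independent effects). For H1 there is no
time contrast, so only the intercept enters.

Fitting: the normal family is estimated by REML; the gamma family by
penalized quasi-likelihood — iterating the working linearization
z = η − (y − μ)/μ², weights w = μ², and fitting a weighted REML linear mixed
model to z at each step. The marginal covariance is block diagonal by
subject, so all linear algebra runs on small per-subject blocks; variance
components are profiled REML estimates optimized on the log scale, and the
dispersion is profiled in closed form. In tests the normal path reproduces
statsmodels MixedLM to ~1e-3 relative on fixed effects, and the gamma path
agrees with R's glmmTMB (Laplace ML) within a few percent of a standard
error on every coefficient. Non-convergence raises a diagnostic error with
the last step size; fewer than two subjects is rejected outright because the
random-effect variance is unidentifiable.

Term tests are Wald F statistics with residual degrees of freedom
(df₂ = n − p). No Kenward–Roger-style small-sample correction is attempted;
the reported df convention is echoed into every output. Partial η² per term
is computed as F·df₁/(F·df₁ + df₂).

EMMs are predictions on the reference grid crossing the requested factor
levels, covariates fixed at the analyzed dataset's means, off-grid factors
averaged (sum-code 0), back-transformed through the link. Standard errors
use the delta method; confidence intervals are computed on the link scale
with the t distribution at residual df and transformed, so they always
contain the EMM (the inverse link reverses the bounds). Post-hoc contrasts
compare grid cells that differ in exactly one factor, test the link-scale
difference with a Wald F, and correct p-values with Holm by default (the
correction method is configurable and recorded). %diff is
100·(EMM_post − EMM_pre)/EMM_pre; a zero reference EMM flags the ratio as
undefined rather than reporting it.

Effect-size labels follow the conventional bands: |rho| < 0.1 very small,
< 0.3 small, < 0.5 medium, else large; partial η² < 0.01 very small, < 0.03
small, < 0.06 small to medium, < 0.09 medium, < 0.14 medium to large, else
large. Published tables in this area are not perfectly consistent near band
edges, so the bands are configurable rather than asserted as anyone's exact
rule.

## Partial Spearman correlation

Motor trials are first averaged to one value per subject and session;
cognitive/symptom scores pass through; pre and post rows are pooled (2N rows
per variable). Every variable and control is midrank-transformed; each
variable's ranks are residualized on the control ranks by least squares with
intercept; the partial rho is the product-moment correlation of residual
pairs. Binary controls are rank-transformed like any variable, which is
equivalent to 0/1 regressors after ranking. p-values use
t = rho·√(df/(1 − rho²)). The statistically standard df = n − 2 − k (k
controls) is the default; df = n − 2 is available as the `pooled` option
because counting pooled pre/post rows without the control adjustment is also
in circulation — the package exposes both and asserts neither. The default
analysis pools pre and post rows; restricting to the post session is a
dataset choice left to the caller. Variables constant after ranking are
excluded with a warning.

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the
conditions under which the package's statistical properties are verified.

*Sway trials.* Quiet-stance COP paths follow an exactly discretized
Ornstein–Uhlenbeck process per planar coordinate — the standard
mean-reverting surrogate for postural sway — with mean reversion 1 s⁻¹ and
diffusion 15 mm/√s (a sway radius of roughly 10–15 mm, plausible for a
one-leg stance of a school-aged child), 25 s at 1,000 Hz. Force channels are
synthesized as body weight (390 N, a ~40 kg child) on Fz with the moments
the COP implies and zero horizontal forces; optional sinusoidal hum (2 N at
50 Hz) is added to the force channels only, so the moment-balance COP equals
the programmed path exactly with hum off. Real sway has structure an OU
process lacks (rambling/trembling components, intermittent control,
non-stationarity), so passing reconstruction oracles demonstrates correct
algebra and filtering, not a validated sway model.

*Jump trials.* The toe marker flies a quintic-eased arc (zero velocity and
acceleration at takeoff and landing, so low-pass filtering does not smear
the endpoints) to a landing point offset by a programmed perpendicular
distance from the target line; the landing plate shows a clean body-weight
step at the landing time.

*Cohorts.* Arm sizes default to 34/14/10 (intervention-with-condition,
waitlist-with-condition, unaffected-with-intervention), ages uniform on
8–13, medication flagged for half the affected subjects. Motor trial errors
are gamma draws with shape 10 (trial-to-trial CV ≈ 32%) whose mean follows
the inverse-link predictor: task baselines 30/25/50 mm (beam, stand, jump),
a 1.25 multiplicative worsening for the condition, a 0.80 time factor and a
0.91 intervention–time interaction factor (≈ −20% pre/post change without
the intervention, ≈ −27% with it — the magnitude pattern such trials
report). Subject random intercepts and time slopes act on the
linear-predictor scale with SDs specified relative to each task's baseline
predictor (12% and 3%): the three tasks' baselines differ by ~2×, so a
single absolute SD would be negligible for one task and infeasible for
another. A draw that drives the predictor non-positive raises a generation
error naming the remedy rather than silently truncating. Cognitive and
symptom outcomes are normal with means, shifts and SDs chosen to emulate
realistic score levels and ~10–20% pre/post changes; within-domain subject
effects share a latent factor (loading 0.7, and 0.5 across motor tasks) so
the correlation analysis has realistic structure to find. Where no published
trial-level dispersions exist these defaults are judgement calls, chosen
once and documented here.

All randomness flows from one root `SeedSequence` with `spawn`-based stream
splitting (subjects / motor / scores), so identical seeds give bit-identical
cohorts and adding draws to one stream never perturbs another.

## Verification sizes and bands

The acceptance-style tests run the chain at these problem sizes, chosen to
keep the whole suite within a few minutes while leaving the Monte-Carlo
bands meaningful:

* interaction recovery: 50 replicate cohorts at arms 34/14/10 with a
  programmed −25% interaction on the mean scale; the mean recovered %diff
  must lie in [−30, −20] (per-replicate SD ≈ 2.7%, so the 50-replicate mean
  is localized to well under a point) and the interaction F test must reject
  in ≥ 80% of replicates;
* type-I calibration: 100 null cohorts; the nominal-5% band [3%, 8%] quoted
  for 500 replicates widens to [1%, 11%] at 100 (binomial 95% envelope
  around that target);
* the outlier screen is checked against an exhaustive interval check on
  1,000 random vectors; the partial-correlation path against its
  residualized-rank brute force at 1e-12.

Determinism is verified end to end: two pipeline runs with the same seed
must produce byte-identical CSV tables.

## File formats and limitations

Trials are exchanged as plain TSV (markers: `<name>_X/_Y/_Z` columns in mm
at 200 Hz; one file per plate with Fx…Mz columns at 1,000 Hz) plus a JSON
meta file; a comma-decimal dialect flag covers European exports, and full
double precision is written so trials round-trip exactly. Binary C3D ingest
is out of scope; the TSV contract carries the same information.

Known limitations: PQL is approximate for the gamma family (its agreement
with Laplace ML is verified in tests but small-sample bias grows as the
shape parameter falls); residual df are anti-conservative for very few
subjects; the intercept–slope correlation is fixed at zero; the generator
does not emulate marker occlusion, biomechanically detailed jump dynamics,
or d2 letter sheets (counts are generated directly). Passing tests on
synthetic cohorts establishes that the estimators recover what was
programmed under the stated model — not that real recordings satisfy that
model.
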
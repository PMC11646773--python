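# posturekit

Analysis toolkit for pre/post balance-intervention trials in children — from
raw force-plate and motion-capture signals to center-of-pressure (COP)
"target error" metrics, generalized linear mixed-model (GLMM) inference, and
partial rank correlations. It is aimed at movement-science groups running
three-arm waitlist-control designs (an affected intervention arm, an affected
waitlist arm, and an unaffected comparison arm) who want the full chain —
signal conditioning, postural metrics, cognitive/symptom score tables,
mixed-model contrasts — as reproducible, tested code rather than ad-hoc lab
scripts.

## What it computes

**Signal conditioning.** Force channels are cleaned of mains hum with a
periodic median filter (the phase-folded median waveform at the hum period is
estimated over the whole record and subtracted), then low-pass filtered with
a zero-phase Butterworth at 40 Hz; marker channels get the Butterworth stage
at 20 Hz.

**COP and target errors.** With plate forces *F* and moments *M* about the
plate origin and surface offset *z₀*, static moment balance gives
COPx = (−My − Fx·z₀)/Fz and COPy = (Mx − Fy·z₀)/Fz; samples under a minimum
vertical load are masked. Three motor outcomes (mm, lower = better):

* *balance beam* — temporal mean distance of the COP from the beam centreline;
* *one-leg stand* — temporal mean distance of the COP from its own barycenter;
* *precision jump* — distance of the big-toe marker from the target line at
  the detected landing.

**Inference.** Motor errors are modelled with a gamma GLMM under the
canonical inverse link, η = 1/μ, with per-subject random intercepts and
pre/post time slopes, fitted by penalized quasi-likelihood; cognitive and
symptom scores use the normal family under REML. Estimated marginal means
(EMMs) are back-transformed predictions on a reference grid with covariates
at their means; pairwise post-hoc contrasts report Holm-corrected p-values,
the pre/post relative change %diff = 100·(EMM_post − EMM_pre)/EMM_pre, and a
per-contrast partial η² = F·df₁/(F·df₁ + df₂). Motor data pass a 1.5×IQR
outlier screen per fit (warning above a 5% removal cap). Associations across
outcomes use partial Spearman correlations: midrank-transform everything,
residualize on the control ranks, correlate the residuals.

**Synthetic cohorts.** A seeded generator produces the whole data structure
with known ground truth: Ornstein–Uhlenbeck sway trials whose moment-balance
COP is exact, jump trials with programmed landing offsets, and cohort tables
whose gamma/normal outcomes follow the same mixed-model structure the
analysis assumes — so every stage can be tested against what was programmed.

## Worked example

`python examples/fit_intervention_glmm.py` simulates a 58-child cohort
(arms of 34/14/10) with a programmed −20% pre/post change without the
intervention and −27.2% with it, fits the gamma GLMM on the balance-beam
errors of the affected subjects, and prints:

```
           term         F            p   eta_p2    effect_label
           Time 87.613833 1.816855e-19 0.133230 Medium to large
        Skating  0.153639 6.952282e-01 0.000269      Very small
   Time:Skating  0.871882 3.508303e-01 0.001527      Very small
       Cov. Age  0.048701 8.254186e-01 0.000085      Very small
Cov. Medication  1.459138 2.275683e-01 0.002553      Very small

estimated marginal means (mm):
Time  Skating   emm   se  ci_low  ci_high
  t1        0 37.46 2.27   33.48    42.52
  t1        1 37.60 1.46   34.94    40.70
  t2        0 29.39 1.53   26.67    32.74
  t2        1 28.13 0.91   26.45    30.04

pre/post contrasts within each arm:
                     pair       p_corr   pct_diff         F   eta_p2    effect_label
Time: t2 - t1 | Skating=0 6.624806e-07 -21.548902 25.287797 0.042480 Small to medium
Time: t2 - t1 | Skating=1 2.078600e-19 -25.193005 88.889811 0.134908 Medium to large
```

Both arms improve (the Time main effect dominates), and the recovered %diff
values (−21.5% / −25.2%) bracket the programmed −20% / −27.2% within
sampling noise for a single cohort of this size. The other scripts under
`examples/` each demonstrate one capability: COP reconstruction, hum
removal, jump scoring, partial correlation, and the full pipeline.

A thin CLI wraps the pipeline for shell use:

```bash
posturekit all --workdir out/ --seed 7
```

writes every result table (`h1_terms.csv`, `h2_terms.csv`, `h2_emm.csv`,
`h2_posthoc.csv`, `pcorr_rho.csv`, …), a correlation heatmap, and a
`report.json` that records stage counts, outlier fractions and every
configuration decision. Identical seeds reproduce all tables byte for byte.

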
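# Methods

This note documents the models, calibrations and numerical choices behind
`carostiff`, in the spirit of a simulator's methods appendix: what is being
emulated, which knobs matter, and what passing tests do and do not establish.

## 1. What the package models

A cross-sectional community screening study of carotid stiffness with a
portable A-mode device: ~1000 adults aged ≥ 30, each measured twice
(10–15 minutes apart), with brachial blood pressure, anthropometry and blood
chemistry collected alongside.  The computational chain is

```
cohort covariates → latent stiffness truth → distension waveform
   → (optional) A-mode envelope frames → wall tracking → beat segmentation
   → stiffness panel → two-trial repeatability → population tables
```

Every stage is deterministic given (configuration, seed); all randomness runs
through `numpy.random.default_rng`.

## 2. Synthetic cohort

Covariate marginals default to the published study population: sex ratio
409:574 (male fraction 0.416), age-decade weights (0.24, 0.34, 0.27, 0.15)
chosen so 61% of subjects are 40–59 years old, 44% of males current/former
smokers, no female smokers, 55% of males current/regular alcohol consumers.
Waist, fasting glucose, triglycerides and HDL-C are truncated normals with
Asian-Indian-plausible means (male waist 88 ± 10 cm, female 79 ± 9 cm; FPG
105 ± 30; TGL 140 ± 60; HDL 42 ± 10 / 48 ± 11 mg/dL).  SBP and DBP are drawn
jointly (r = 0.6, 131 ± 17 / 80 ± 10 mmHg); each pressure is observed as two
replicate readings with 2.5% relative noise (one per trial).  The joint
covariate distribution is not published; marginals are otherwise independent.
This is the main idealisation: real risk factors co-occur, so simulated risk
counts have less structure than field ones.  Statin users default to 0%
because they were excluded from the modelled study at enrollment.

## 3. Latent stiffness truth

β is the single generative primitive.  A subject's `beta_true` is the
published regression

```
β = 0.087·Y_age + 1.361·V_sex + 0.046·P_sys − 0.076·P_dia
    + 0.035·Y_smk + 0.124·N_cmr + 2.099          (V_sex: 1 male, 2 female)
```

evaluated on the replicate-mean pressures, plus Gaussian noise, floored at
β = 1.  The noise SD is derived analytically from the realized linear
predictors: σ = sd(lp)·√((1−R²)/R²) with the published R² = 0.65, so the
refitted model recovers that explained variance by construction rather than by
tuning.  Ep, AC, PWVβ and DC are *derived* from the simulated geometry and
pressures, never generated from their own published regressions — those
coefficient sets predict implausible central values (e.g. the PWVβ intercept
plus DBP term alone gives ≈ 6.8 m/s for a normotensive adult) and are kept
only as reference constants.  This guarantees internal mechanical consistency
(the Bramwell–Hill identity PWVβ²·2ρ = β·Pd holds exactly) at the cost that
the simulated cohort's marginal index distributions inherit any bias in the β
equation: evaluated at plausible covariate means it yields mean β ≈ 8.5
versus the study's reported 7.37, and hence a mean distension of ≈ 0.30 mm
versus the reported 0.36 ± 0.14 mm.  We keep the printed equation as-is and
assert the distension only within the reported ±1 SD band.

End-diastolic diameter is an independent truncated normal, 5.35 ± 0.5 mm in
[4, 8] mm.

## 4. Waveform and echo synthesis

Systolic strain is set to `ln(Ps/Pd)/beta_true`, inverting the β formula, so
the noise-free chain returns `beta_true` to machine precision — the central
round-trip contract.  Pulse morphology is a free choice (only Ds and Dd enter
the indices): a raised-cosine upstroke over 30% of the cycle, then a
`(1+x)e^(−x)` relaxation with τ = 0.08·period.  That relaxation starts with
zero slope (the systolic peak is a smooth extremum, not a corner) and has
fully flattened by late diastole; both properties matter numerically because
beat extraction reads smoothed extrema (§5).  Beat period and rise time are
quantized to the 100 Hz diameter frame grid so extrema fall on samples — a
simulation convenience with no physiological content.  Per-sample additive
diameter noise defaults to 5 µm.

Echo frames place two Gaussian lobes (σ = 0.3 mm, distal amplitude 0.85) at
`centre ∓ D/2` with the lumen centre at 17.6 mm, on a 5–35 mm depth window
sampled at 40 MHz (depth step ≈ 19 µm, c = 1540 m/s, depth = c·t/2).
Multiplicative lognormal speckle (σ = 0.05) models envelope fluctuation.
RF-level physics, scatterer speckle and beam geometry are out of scope; the
envelope model is the simplest signal for which peak-based tracking is
well-posed, so tracking results here bound what a real device can do only
from above.

## 5. Wall tracking and beat segmentation

Detection picks the two highest-prominence envelope peaks at ≥ 2 mm
separation; confidence is the weaker/stronger prominence ratio.  Tracking is
a causal gated algorithm: per frame and wall, the gated segment (±1.5 mm) is
matched to the previous frame's segment by normalized cross-correlation
searched within the gate, with 3-point parabolic sub-sample lag refinement;
the NCC peak value is the confidence, and > 10 consecutive frames below 0.5
raise track loss.  The *reported* depth is then re-anchored to the envelope
peak inside the updated gate via a least-squares parabola on log-amplitude
over ±0.6 mm — exact for a Gaussian lobe, and drift-free, whereas integrating
frame-to-frame sub-sample lags random-walks at the sub-micron level.  Peak
(not leading-edge) tracking is a deliberate choice; with it, noise-free wall
positions are recovered to ≪ half a depth sample.

Beat segmentation detects diastolic minima on a quartic Savitzky–Golay
smoothed copy (window ≈ 70 ms) with inter-beat spacing from the 40–180 bpm
heart-rate bounds.  Dd/Ds are the smoothed values at the detected extrema: an
LS-quadratic/quartic value is unbiased at a smooth extremum, while min/max of
the raw noisy series would bias distension upward by order one noise SD.  A
beat is accepted iff its distension lies in 0.05–1.5 mm, its duration is
consistent with the heart-rate bounds, and its shape correlates ≥ 0.8 with
the median beat.  Indices are computed on Ds/Dd averaged over accepted beats
(the device-like "index on averages" order); per-beat averaging is available
as an option and differs only at second order in beat variability.

Residual accuracy: noise-free round-trip β error ≤ 1e−3 relative (the beat
template's corner at the diastolic onset contributes ~0.1 µm of smoothing
bias); at default noise the median |β̂−β|/β is ≈ 2–4%, dominated by
extremum-selection bias ∝ per-frame position noise.

## 6. Two-trial replication and repeatability calibration

Trial 2 re-draws the measured geometry about trial 1's truth: end-diastolic
diameter × (1 + ε_d) and strain × (1 + ε_s) with ε_d ~ N(0, 0.117²),
ε_s ~ N(0, 0.22²), then rebuilds the waveform with fresh noise.  Both SDs are
analytic calibrations fixed in the configuration:

* P(RD ≤ 15%) = 0.80 for a single lognormal-free relative perturbation
  requires σ_d = 0.15/z₀.₉₀ = 0.117046 — reproducing the study's "≈80% of
  diameter pairs within RD ≤ 15%";
* the implied two-trial β relative error √(0.22² + 0.117²) = 0.249 gives a
  mean RD of 100·0.249·√(2/π) ≈ 19.9%, matching the reported ≈ 20.5%;
* BP replicate noise of 2.5% gives mean BP RD ≈ 2.8% (< 5% as reported).

The repeatability module computes RD = 100·|x₁−x₂|/|mean|, the SD of raw
differences, the RD ≤ 15% fraction, and the fraction outside mean ± 1.96 SD
(limits of agreement).  "Group average RD" is the mean (not median) of
per-subject RDs.  An exactly zero pair mean raises an error rather than
mapping to 0 or ∞ — impossible for physiologic positive quantities, so it
flags corrupt data.

## 7. Risk rules and categories

The five binary criteria use the printed boundary semantics exactly: waist
≥ 90/80 cm (M/F); TGL ≥ 150 mg/dL or treatment; HDL < 40/50 mg/dL (M/F) or
treatment; SBP ≥ 130 or DBP ≥ 80 mmHg or antihypertensive treatment; FPG
strictly > 100 mg/dL or treatment.  Three or more criteria define high risk.
Treatment satisfies the high-BP *criterion*, but the BP *category* (ACC/AHA
normal / elevated / stage 1 / stage 2 / crisis) is always computed from
measured pressures, with "higher category wins" when SBP and DBP disagree —
the standard convention.  A missing HDL assay excludes the subject from risk
analyses.  A single lipid-treatment flag satisfies both lipid criteria (the
questionnaire granularity is not modelled further).

## 8. Population statistics

* Strata: sex × age bands {30-39, 40-49, 50-59, ≥60}; the
  hypertension/diabetes-free subgroup drops subjects meeting the high-BP or
  elevated-FPG criterion (threshold or treatment).
* Group tests: Student t with pooled variance for two groups (not Welch),
  one-way ANOVA otherwise.
* Quintiles: linear-interpolation percentiles at 20/40/60/80, boundary values
  assigned to the lower quintile.
* Odds ratios: logistic regression on quintile indicators (Model 1) and
  additionally continuous age in years (Model 2), 95% Wald intervals.  A
  quintile with constant outcome is reported flagged with null CIs rather
  than a divergent estimate.  With a single binary predictor the fitted OR
  equals the 2×2 cross-product ratio — the closed-form contract the tests
  enforce.
* Trend: Cochran–Armitage chi-square with equally spaced scores 1..5 (1 df),
  hand-coded because no installed package exposes it publicly; it satisfies
  the identity χ² = N·r² with the score–outcome Pearson correlation, which is
  the independent oracle used in testing.
* Contrasts: per-BP-category (and smoking-duration band) means, deltas versus
  the reference group, and percent changes rounded to one decimal — the
  reporting precision of the emulated study.
* Predictive models: OLS of each index on (age, sex code, SBP, DBP,
  smoking-years, risk count) with intercept via statsmodels; designs with
  condition number > 1e10 or zero-variance columns raise a singular-fit error.

## 9. Problem sizes and determinism

Default study size is 983 subjects with 10 beats per trial at 100 Hz.  The
validation suites use: 10 subjects for noise-free round-trip checks, 500 for
the noisy round-trip median, 1000 for repeatability calibration, 2000 for
regression recovery/R², and 200 replicates (×4 quintile CIs) for null
coverage — sizes at which the Monte-Carlo error of each checked statistic is
several times smaller than its acceptance band.  Identical seeds reproduce
every artifact bit for bit; the pipeline writes a SHA-256 manifest and skips
recomputation when outputs already match it.

## 10. Known limitations

* Independent covariate marginals (no published joint distribution); risk
  clustering is therefore weaker than in the field.
* The β regression drives all indices; cohort-level means of Ep/AC/PWVβ are
  mechanically consistent but need not match the published cohort means, and
  mean distension sits ~15% below the published value (§3).
* The envelope model is Gaussian-lobe + lognormal speckle; no RF simulation,
  attenuation, or probe motion other than the inter-trial repositioning model.
* Printed percent-change checks use the published group baselines and deltas
  as inputs; group p-values of the original cohort are not reproducible
  without the field data and are not asserted.
* One published percent change (β, stage 2: Δ 0.56 on baseline 6.62 → 8.46%)
  rounds to 8.5, not the printed 8.4, and the stage-1 AC percent is printed
  without its sign; these are reported but not asserted to the printed
  decimal.
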
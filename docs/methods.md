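# Methods

## The composite biomarker

Serum brain-derived neurotrophic factor (BDNF) runs lower in major
depressive disorder than in healthy controls, and antidepressant response is
thought to act through recovered neuroplasticity. The **neuroplasticity
index (NI)** divides the serum BDNF concentration (pg/ml) by the same-day
HAMD-24 depression score, giving circulating neurotrophic signal per unit of
symptom burden. **NI enhancement** over a treatment interval is the signed
difference `NI(later) − NI(earlier)`. The package's central analysis asks
whether NI enhancement measured *early* in treatment (day 7 of a
single-arm trial; day 4 of a two-arm trial) predicts *final* treatment
response at day 28, where response ("quasi-effective") is a HAMD-24
reduction rate `(baseline − final)/baseline ≥ 0.60`, with an inclusive
boundary.

Both divisions are only defined on same-day measurement pairs; no
interpolation across visits is performed. A post-treatment HAMD-24 of 0
(full remission) leaves NI undefined at that visit; the visit is dropped
from NI analyses and logged rather than floored, since any floor is
arbitrary and a remitted subject no longer needs prediction.

## Statistical machinery

All inference is two-tailed at α = 0.05.

* **Pearson correlation** (`stats.pearson`): `r` from the product-moment
  definition, `t = r√((n−2)/(1−r²))`, p from Student's t with n−2 df.
* **One-way repeated-measures ANOVA** (`stats.rm_anova_oneway`): total SS
  partitioned into subjects, time and error strata by direct summation;
  `F = MS_time/MS_error`. Sphericity is corrected by the
  **Greenhouse–Geisser ε** computed from the double-centered sample
  covariance `S̃` of the conditions, `ε = tr(S̃)²/((k−1)·ΣS̃²ᵢⱼ)`, bounded in
  `[1/(k−1), 1]` (exactly 1 under compound symmetry and for k = 2); both F
  df are multiplied by ε for the headline p. Greenhouse–Geisser rather than
  Huynh–Feldt is used because the fractional df this style of analysis
  reports imply it; the correction can be switched off.
* **Post-hoc contrasts** (`stats.posthoc_vs_baseline`): paired t of each
  later visit against baseline; uncorrected by default (Bonferroni
  available) — both are reported in the pipeline output.
* **Mixed (split-plot) ANOVA** (`stats.mixed_anova`): drug tested against
  subjects-within-groups; time and drug × time against the subject × time
  residual, with ε from the pooled within-group covariance. With unequal
  group sizes the decomposition uses group-size-weighted sequential sums of
  squares; components always add to the total SS exactly.
* **Two-sample comparison**: Welch's unequal-variance t with
  Welch–Satterthwaite df — a robust default given no reason to assume equal
  variances between patients and controls.
* **ROC** (`roc.roc_curve`): thresholds at the distinct score values,
  trapezoidal AUC over the full staircase, which with ties credited ½
  equals the pair-counting (Mann–Whitney) statistic; a hand-written
  pair-counting estimator is retained as an independent oracle and the two
  agree to 1e-12 by test. Baseline BDNF is scored with *lower = positive*
  (patients run low); NI enhancement with *higher = positive*. Operating
  points maximise Youden's J (ties broken toward higher sensitivity, then
  lower threshold); closest-to-(0,1) could be substituted but J is the
  conventional default when the selection rule is unreported. Confidence
  intervals are off by default; a seeded percentile bootstrap is available.

Only t/F/normal tail probabilities come from `scipy.stats`; every statistic
itself is computed from its definition, and the test-suite cross-checks them
against `scipy` and `pingouin`.

## The synthetic cohort generator

Patient-level data for this design are not publicly deposited, so
`simulate` builds cohorts carrying the structure the analyses presuppose.
Per subject, with latents `t, s ~ N(0,1)` and `g ~ N(1, σ_g²)`:

```
L     = σ_h(−c·t + √(1−c²)·s)                    subject's HAMD level
HAMD_d = round(μ_H + δH(arm,d)·g + L + e_d)       e ~ N(0, sd_H²), floor 0
BDNF_d = μ_B − deficit + δB(arm,d)·g + τ·t + u_d  u ~ N(0, sd_B²), floor 1 pg/ml
```

`t` is a stable *neuroplasticity trait*: it raises BDNF (scale τ) at every
visit and, through the coupling `c ∈ [0,1]`, lowers HAMD — producing the
negative baseline BDNF–HAMD correlation and the NI autocorrelation across
visits. `g` is a *treatment-responsiveness amplitude* multiplying the arm's
mean trajectory `δH, δB` in both modalities; it is the minimal additional
linear-Gaussian ingredient that couples early NI enhancement to final
reduction rate (without it, final response would be pure visit noise and no
early marker could predict it). QIDS-SR16 and PHQ-9 are noisy affine
functions of the same within-visit severity state, clipped to instrument
ranges. Enrollment floors (HAMD-24 ≥ 20, QIDS-SR16 ≥ 5 at day 0) are
enforced by resampling the whole subject, keeping the accepted baseline
distribution smooth; BDNF missingness is whole-subject (as when blood was
never drawn), never visit-wise.

Defaults (one per-field rationale; the assay scale carries no published
distribution, so values are calibrated to reproduce the qualitative pattern,
not any particular cohort):

| parameter | default | unit | note |
|---|---|---|---|
| `control_bdnf_mean` / `control_bdnf_sd` | 26 000 / 3 400 | pg/ml | serum ELISA scale (~26 ng/ml) |
| `patient_bdnf_deficit` | 8 000 | pg/ml | puts the case/control AUC near 0.95 |
| `hamd_baseline_mean` / `hamd_baseline_sd` | 26 / 4 | points | moderate-severe cohort over a ≥20 floor |
| `trait_sd` τ | 3 000 | pg/ml | between-subject BDNF spread |
| `trait_coupling` c | 0.8 | – | baseline BDNF–HAMD r ≈ −0.6 after truncation |
| `response_dispersion` σ_g | 0.35 | – | responder rates ≈ 0.6 (yueju-like) vs ≈ 0.02 (SSRI-like) |
| `measurement_sd_hamd` / `measurement_sd_bdnf` | 2 / 1 500 | points / pg/ml | visit-level noise |
| `missing_bdnf_per_arm` / `missing_bdnf_trial1` | 4 / 1 | subjects | blood-draw failures (n = 14 per BDNF analysis) |

The arm profiles make the herbal-arm HAMD fall from day 4 with BDNF rising
at every blood draw, and the SSRI-like arm improve more modestly with BDNF
flat by day 28 (mild early dip). The SSRI-like trajectory is deliberately
calibrated to the *scarcity of ≥60% reducers* that makes its prediction ROC
infeasible — a stylization of that observation, at the cost of
understating that drug's average symptom relief.

### Analytic structure (`expected_structure`)

Parameter-recovery tests need an oracle independent of the sampler.
Because the model is linear-Gaussian below the ratio, the implied population
summaries are computed without sampling:

* baseline means and the baseline BDNF–HAMD correlation under the one-sided
  enrollment truncation, in closed form via the Mills ratio;
* NI autocorrelation between day 0 and the early blood day by deterministic
  Gauss–Hermite quadrature over `(t, s, g)` with Gauss–Legendre integration
  of the `1/H` moments, conditioning on the truncation event.

Approximations, each verified harmless at the defaults: score rounding to
integers is ignored (<1% of visit variance), the QIDS floor co-truncates
<1% of subjects, and `1/H` moments integrate over `H ≥ 0.5` (a zero score
leaves NI undefined; the excluded mass is ~1e-5 at the early day). The
quadrature is converged to ~1e-12 in node count and agrees with large
Monte-Carlo runs of the full generator within replicate-based Monte-Carlo
error.

Two facts about ratio statistics discovered during validation and encoded
in the tests:

* the sample Pearson correlation of NI across visits is **heavy-tailed**
  (rare near-remission scores dominate), so Monte-Carlo comparisons use
  standard errors estimated across independent replicates rather than the
  naive `(1−ρ²)/√n`;
* even with all latent couplings switched off, early NI enhancement retains
  predictive signal for the reduction rate because both contain the baseline
  visit (regression to the mean). The exact null for the prediction ROC is
  therefore *label exchangeability*, and the type-I calibration test
  shuffles responder labels rather than relying on an uncoupled generator.

## What the generator does and does not emulate

It reproduces: enrollment floors, both visit schedules (scales on days
0/7/14/28 and 0/4/7/14/28; blood on 0/7/28 and 0/4/28), whole-subject BDNF
missingness, lower patient baseline BDNF, arm-specific symptom/BDNF
trajectories, NI autocorrelation, and the early-enhancement → response
coupling. It does not emulate: dropout, item-level instrument structure,
placebo response dynamics, pharmacokinetics, assay batch effects, or
non-Gaussian biology. Passing tests therefore show the *pipeline* is
correct and well-calibrated under a plausible data-generating process —
not that the clinical effect sizes themselves are reproduced from real
patients.

## Numerical choices and degenerate inputs

* Sums of squares below `1e-12·(SS_total+1)` are treated as exact zeros so
  null effects report F = 0, p = 1 instead of 0/0.
* Zero-variance paired differences degenerate to t = 0, p = 1 (identical
  pairs) or t = ±∞, p = 0 (constant nonzero shift); Welch's t handles the
  all-constant case the same way.
* `|r| = 1` reports p = 0 exactly rather than overflowing the t transform.
* CSV round-trips are bit-exact: floats are written with shortest
  round-trippable repr and parsed with correctly-rounded `float()`.
* Analyses are complete-case per figure (each declares its own n); nothing
  is imputed, matching how per-analysis n varies in this design
  (e.g. 15 subjects for scales vs 14 for BDNF).
* The prediction ROC for an arm is skipped when either response class has
  fewer than `min_roc_class_count` (default 3) subjects — a curve from one
  or two positives is not interpretable.

## Problem sizes

Default cohorts are 15 (+11 controls) and 2 × 18 subjects, matching the
emulated design. The test-suite uses: 250 random instances for each oracle
equivalence; 1 000 replicates for the ANOVA type-I calibration and 300 for
the permutation-ROC calibration; 500 subjects per arm for parameter
recovery; and 6 × 20 000 subjects for the Monte-Carlo check of the analytic
oracle. The full suite runs in well under a minute after import.

## Known limitations

* The split-plot ANOVA assumes complete within-subject data (complete-case
  first); no mixed-effects or MANOVA alternative is offered.
* The Greenhouse–Geisser ε estimator is conservative under true sphericity
  (the uncorrected p is also reported).
* Population NI autocorrelations involving day 28 are intentionally not
  reported by `expected_structure`: near remission the ratio's moments are
  dominated by the smallest scores and the summary is unstable; empirical
  day-28 correlations are still computed by the pipeline.
* The escitalopram-like arm is a stylization (see above); comparisons of
  *absolute* symptom relief between arms should not be read off the
  defaults.
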
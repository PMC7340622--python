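# Methods

This note documents the model behind `exclusim`: what the synthetic-cohort
generator assumes, how every default was chosen, what the two diet-effect
estimators are, how the exclusion sweep and the sensitivity experiments are
operationalized, and what the simulations can and cannot show about real
feeding-trial data.

## 1. The scientific setting

A randomized feeding trial compares low- (20%), moderate- (40%) and high-
(60%) carbohydrate diets during weight-loss maintenance, with total energy
expenditure (TEE) by doubly-labeled water (DLW) as the outcome. A post-hoc
reanalysis excluded participants with high "Unaccounted Energy"
(UE = |intake − expenditure − ρ_fm·ΔFM|) as putatively non-adherent and
found the diet effect shrinking as exclusions deepened. The package
implements the counter-argument as a simulation: when UE is driven by
size-scaled measurement error, excluding on it biases the estimate toward
the null even with a fully real effect and fully adherent participants,
and covariate adjustment removes part (not all) of that bias.

## 2. Cohort generator

One row per participant; all randomness flows from a single master seed
through named per-stage child seeds (`numpy` `SeedSequence` spawning), so
any stage is replayable in isolation.

### 2.1 Baseline covariates

Calibrated to the published marginals of the emulated 145-person cohort.

| quantity | distribution | default | rationale |
|---|---|---|---|
| sex | Bernoulli(female) | 69% female | printed percentage |
| age (y) | lognormal | median 35.7, log-SD 0.5586 | log-SD solved from the printed IQR (24.1, 51.2): log(51.2/24.1)/(2·0.6745) |
| weight (kg) | normal, sex-shifted | mean 91.3, SD 18.3, male−female gap 14 | printed mean/SD; the sex gap is a population-typical value, injected so that sex, size and expenditure are coupled as in real cohorts; the marginal mean/SD are preserved exactly by shrinking the within-sex SD |
| height (cm) | normal, sex-shifted | 168.0, SD 10.1, gap 13 | as for weight |
| insulin-30 (uIU/ml) | lognormal, copula-linked to weight | median 113.5, log-SD 0.5838, r = 0.3 | printed median/IQR; the weight link encodes that heavier participants secrete more insulin |
| body fat (%) | normal by sex | female 43.6 / male 34.0, SD 5 | sex means solved so the mixture reproduces the printed 40.7 (6.4) |
| race / Hispanic | categorical | printed fractions | table variables only; they feed nothing downstream |
| enrollment cohort | uniform over 3 | 3 cohorts | the trial enrolled over several years; the count is an assumption (configurable) |
| run-in loss (%) | normal, regressed on baseline TEE | 10.5, SD 1.6, slope −1.0 %/SD(TEE) | printed mean/SD; the negative TEE link (−0.63 correlation) makes high-expenditure participants lose less relative weight, matching the direction of the published UE-group split |

### 2.2 Expenditure model

Pre-weight-loss TEE is linear in covariates:

```
TEE0 = 2946 + 200·male + 28·(w − 91.3) + 8·(h − 168) − 4·(age − 41.7) + ε,
ε ~ N(0, 410²)
```

Intercept and residual SD are solved so the marginal is 3008 ± 718 kcal/d.
The coefficients are ordinary DLW-regression magnitudes; together with the
sex-shifted anthropometrics they give a total male−female TEE gap of
~700 kcal/d.

Maintenance TEE after the run-in is `L = TEE0 − 29·runin_loss` (kcal/d per
percent lost, size-independent). 29 kcal/d/% puts mean maintenance TEE at
~2700 kcal/d, consistent with the printed start-of-test intake once the
accounting gap (below) is applied. The true diet effect added to L is

```
effect = cim_slope · (40% − carb_consumed)/10% · (w_postloss / 82 kg)
```

with `cim_slope = 62.5` kcal/d per 10% carbohydrate decrease, i.e. a
**250 kcal/d low-vs-high contrast at the 82-kg reference weight**,
matching the trial-scale estimate the controversy is about. (The
theoretical prediction usually quoted is ~50 kcal/d per 10%; the generator
is deliberately calibrated to the study-scale contrast, and the slope is a
single config field for anyone wanting the other convention.) Scaling by
post-loss weight makes the *weight-normalized* effect exactly constant
across body sizes — which is precisely why the normalizing estimator is
partially protected from size-selective exclusion. A shared subject-level
biological offset (SD 50 kcal/d, size-scaled) joins both test-phase
timepoints.

### 2.3 Measurement model

All error SDs are multiplied by the participant's energy-flux scale
`s = L / mean(L)` (floored at 0.4): bigger metabolisms have proportionally
bigger absolute errors. This heteroscedasticity is the engine of the
UE-covariate confounding.

| error | SD at s = 1 | rationale |
|---|---|---|
| DLW TEE (baseline, mid, end) | 160 kcal/d | ~6% CV, within the published precision range of DLW |
| intake record noise | 100 kcal/d | weighed provision records of a feeding study are precise |
| fat-mass-change rate | 0.003 kg/d | isotope-dilution body-composition precision spread over the test phase |
| subject intercept | 50 kcal/d | day-to-day biology shared across timepoints |

Measured intake additionally carries systematic structure: records are
anchored to the provision schedule, so

```
EI_measured = (1 − γ)(L + θ·effect) + noise,   γ = 0.18, θ = 0.5.
```

γ is the accounting gap (unconsumed/unabsorbed provided food plus
bookkeeping loss); 0.18 reproduces the printed start-of-test intake mean
(0.82 × 2700 ≈ 2214 kcal/d) and puts the simulated UE median at
~438 kcal/d. θ is the fraction of the diet-induced TEE change that the
provision adjustments capture; 0.5 reflects adjustments chasing weight
change with a lag. True intake always equals true expenditure (weight
maintenance), so *true* unaccounted energy is zero for everyone.

### 2.4 Non-adherence and the RQ pathway

A fraction f of each arm (exact count `round(f·n_arm)`) drifts
`nonadherence_drift` (default 0.5, the conservative halfway point) of the
way toward 40% carbohydrate, carbohydrate displacing fat at fixed protein.
Consequences: the true effect is recomputed from the consumed diet, and
the food quotient of the consumed diet diverges from the prescribed one the
DLW calculation assumes, multiplying measured TEE by the Weir-equation
bias ratio `(3.941/RQ_assumed + 1.106)/(3.941/RQ_true + 1.106)`. A
low-carbohydrate drifter's apparent TEE is *inflated* ~3%; a
high-carbohydrate drifter's deflated ~2.5%. The DLW layer starts at CO₂
production; isotope kinetics are out of scope, and protein is folded into
a fixed fuel RQ of 0.835 (no urinary-nitrogen term — a second-order
refinement for a ratio-based sensitivity analysis).

## 3. Unaccounted energy, median split, quantile bins

UE is computed from the **final** test-phase intake and expenditure (the
reanalysis under study used final dietary intake and body composition), the
fat-mass-change rate being a single test-phase quantity; a time-averaged
variant is a config switch. The median split sends values ≤ median to the
low group, which yields the 73/72 split at n = 145; all-equal input
degenerates to an empty high group with a warning. Quantile bins (default
36) rank by *descending* UE with ties broken by participant id; bin b holds
ranks `(round((b−1)n/36), round(bn/36)]`, so sizes differ by at most one
and at n = 145 exactly one bin holds 5 participants. An optional
fat-free-mass correction term exists (off by default) for comparison with
other published UE variants.

## 4. Effect estimators

Outcome: change in measured TEE from the pre-weight-loss baseline,
averaged over the two test-phase timepoints. With two balanced timepoints,
no arm-by-timepoint interaction and compound-symmetry within-subject
covariance, the repeated-measures arm contrast equals the OLS contrast on
subject means; the package fits the subject-mean OLS (statsmodels), with
p-values from the t distribution at residual degrees of freedom.

* **Unadjusted**: plain kcal/d change, arm fixed effects only — emulating
  the original exclusion reanalysis.
* **Adjusted**: change normalized to the 82-kg reference post-loss weight
  (`Δ·82/w_postloss`), with fixed effects for sex, age, baseline weight,
  height, run-in % loss, measured baseline TEE, log insulin-30 and
  enrollment cohort — emulating the covariate-adjusted reanalysis, which
  introduced the normalization.

The reference weight 82 kg is the mean post-loss weight (91.3 × 0.895), so
the two estimators agree in expectation on the full cohort. Analysis is
intention-to-treat by assigned arm; a per-protocol flag drops non-adherent
rows first. Rank-deficient designs raise an error naming the collinear
columns; subsets must contain both extreme arms with ≥ 3 participants.
Only the low-vs-high contrast is reported; the moderate arm contributes
residual information.

## 5. The exclusion sweep

Bins are frozen on the full cohort; for k = 0..18 bins 1..k are dropped and
both estimators re-fitted. Attenuation at step k is `1 − est_k/est_0`,
always within-estimator. Steps whose subset cannot support a fit are
recorded as undefined with the reason. **No trend line is ever fitted
across sweep points** — successive estimates share most of their data and
violate every regression assumption; only the curve is reported or
plotted.

Across replicates, mean attenuation is aggregated as
`1 − mean(est_k)/mean(est_0)` (attenuation of the mean effect): the mean
of per-replicate ratios carries a Jensen bias of order −0.02 from the noisy
denominator, which would masquerade as spurious (anti-)attenuation in null
scenarios. Per-replicate ratios are still used where a paired comparison
is the point.

## 6. Sensitivity suite

* **Non-adherence sweep**: for each f on a 0–0.7 grid, simulate cohorts
  with that non-adherence, apply the analyst-side *conservative RQ
  correction* — divide each arm's measured TEE by the expected bias ratio
  `1 + f·(r_drift − 1)` — and fit the adjusted ITT effect. The correction
  is mean-accurate when the assumed fraction matches the truth, so what
  survives is the genuinely diluted signal; the reported bound is the
  largest f whose median two-sided p across replicates stays below 0.05
  (a median-p operationalization of "remains significant" for a
  stochastic suite). At the defaults the bound is 0.7, comfortably past
  half the cohort.
* **Symmetric vs one-sided tails**: the symmetric variant removes both
  tails of the intake:expenditure ratio *centered on its arm median*
  ("higher and lower than average" within each diet group) — an
  error-symmetric exclusion that leaves the mean effect intact. The
  one-sided comparator removes the same total count from the top of the
  UE distribution, which depletes one tail of the TEE-error distribution
  and attenuates the effect.
* **Tail-depletion diagnostic**: simulation-only (it needs the latent
  error columns and raises on real-data cohorts). Reports the
  point-biserial correlation of the exclusion flag with the signed and
  absolute test-phase TEE error, and the retained-mean signed error per
  sweep step. Under UE exclusion the signed correlation is strongly
  positive (~0.4): the procedure preferentially discards participants
  whose TEE was measured too high, and the retained mean error drifts
  monotonically negative as k grows.

## 7. What the simulations show, and what they cannot

With all noise off and full adherence the pipeline is exact: measured
equals true, UE ≡ 0, and the estimators return the programmed contrast to
machine precision — the test suite pins these identities. At the default
study conditions the suite computes, among others: unbiased recovery of
the 250 kcal/d effect by both estimators without exclusions; UE-group
baseline imbalances in the published directions (high-UE more male,
heavier, higher TEE, less run-in loss); mean attenuation at half-exclusion
of roughly 0.15–0.20 for the raw estimator versus roughly 0.10–0.14 for
the adjusted one; and a null attenuation under exclusion on an independent
variable.

Two quantitative caveats are worth stating plainly, because they are
properties of the setting, not implementation artifacts. First, at
n = 145 with realistic DLW noise, a single sweep realization is very
noisy: the per-replicate SD of the attenuation difference between the two
estimators is ~0.10, so the adjusted-vs-unadjusted ordering holds in only
about 60–70% of individual replicates even though its mean is clearly
positive — single-dataset attenuation figures (including published ones)
carry large sampling error. Second, because the exclusion depletes
predominantly one tail of the signed error, the correlation of the
*absolute* error with exclusion is intrinsically modest (mean ~0.12
against a sampling SD of ~0.08 at n = 145); the signed-error correlation
is the sharp signature.

What passing simulations do **not** show about real data: the generator's
covariate joint distribution is marginal-calibrated, not a copy of any
real cohort (weight/height are sex-shifted normals, independent of age);
intake under-accounting is a single proportional gap; there is no
missingness by default (the real trial's three missing TEE values are not
emulated; a missingness switch exists for robustness checks); true intake
exactly equals expenditure, so real-world weight drift is absent; and the
UE-covariate coupling strength was set to reproduce published group
splits, not estimated from individual-level data. The published 42%/9%
attenuation pair is a property of the original (non-deposited) dataset
and is deliberately not a calibration target; the package reproduces the
direction and mechanism, not those two numbers.

## 8. Numerical conventions

Chi-squared tests use the Pearson statistic without continuity correction
(this reproduces the published count-based p-values exactly); two-sample
t-tests are pooled-variance Student tests (the Welch variant does not
match the published rows any better and the pooled form is the printed
footnote's "independent t-test"); the Wilcoxon rank-sum uses mid-ranks,
tie-corrected normal approximation with 0.5 continuity correction, and
full enumeration when n₁+n₂ ≤ 12 (with heavy ties the two disagree by up
to ~0.08 at that size; for continuous data they agree within 0.02). No
multiplicity adjustment is applied across baseline-table rows. Cohort
CSVs round-trip losslessly at 1e-9; configs serialize to YAML/JSON with
unknown keys rejected.
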
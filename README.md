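# exclusim

**Post-randomization exclusion bias in controlled feeding trials, as an
executable model.**

`exclusim` is a simulation and analysis toolkit for a specific
methodological controversy in nutrition science: what happens to the
estimated effect of diet composition on total energy expenditure (TEE) when
participants of a randomized feeding trial are excluded *after*
randomization based on **Unaccounted Energy (UE)** — the absolute gap
between measured energy intake and expenditure, corrected for body-fat
change:

```
UE = | EI − TEE − ρ_fm · ΔFM |,        ρ_fm = 9441 kcal/kg
```

A large UE has been read as evidence of diet non-adherence and used to
justify excluding participants from a major carbohydrate-vs-fat feeding
trial. But UE is a post-randomization variable built from three noisy
measurements, each of whose errors scales with body size. Excluding on it
(1) destroys randomization — the retained arms become observationally
confounded by sex, weight and baseline TEE — and (2) selectively depletes
one tail of the TEE measurement-error distribution, dragging the estimate
toward the null even when the diet effect is entirely real.

The package is aimed at biostatisticians and trial methodologists who want
these claims as reproducible simulation experiments rather than prose: a
calibrated synthetic cohort generator with latent truth, the UE machinery,
two diet-effect estimators, the sequential quantile-exclusion sweep,
baseline-imbalance tables, and a respiratory-quotient sensitivity suite.

## The model in brief

Each simulated cohort emulates a 145-person, three-arm (20/40/60%
carbohydrate) weight-loss-maintenance trial:

* baseline covariates matched to the trial's published marginals (69%
  female, weight 91.3 ± 18.3 kg, pre-weight-loss TEE 3008 ± 718 kcal/d,
  run-in loss 10.5 ± 1.6%);
* a true diet effect on TEE of **62.5 kcal/d per 10% decrease in dietary
  carbohydrate**, scaled by post-loss body weight — i.e. a low-vs-high
  contrast of **250 kcal/d** at the 82-kg reference weight;
* independent Gaussian measurement errors on intake, DLW expenditure and
  fat-mass change whose SDs scale with individual energy flux, plus a
  systematic intake-accounting gap — so UE is driven by error, not
  misbehavior;
* an optional non-adherence mixture whose eaters drift toward 40%
  carbohydrate, diluting their true effect and biasing their measured TEE
  through the Weir-equation respiratory-quotient (RQ) assumption:
  `TEE_apparent / TEE_true = (3.941/RQ_assumed + 1.106) / (3.941/RQ_true + 1.106)`.

Because the truth is latent but recorded, selection bias is directly
measurable: you can correlate the exclusion flag with the actual
measurement errors.

## Worked example

```python
from exclusim import (ScenarioConfig, add_ue_columns, sample_cohort,
                      sequential_exclusion)

config = ScenarioConfig(seed=1)
cohort = add_ue_columns(sample_cohort(config), config)
res = sequential_exclusion(cohort, config)
print(res.table[["k", "n_retained", "estimate_unadjusted",
                 "estimate_adjusted"]].round(1).head(3))
```

```
 k  n_retained  estimate_unadjusted  estimate_adjusted
 0         145                221.4              218.8
 1         141                214.0              216.2
 2         137                189.5              192.8
```

Every participant in this cohort is perfectly adherent and the programmed
effect is 250 kcal/d (this realization estimates it at ~220 ± 40). As the
highest-UE quantile bins are dropped (k = 1..18, removing half the cohort),
the estimates decline — pure selection bias. Averaged over replicates, the
plain kcal/d estimator loses roughly a fifth of the effect by k = 18 while
the weight-normalized, covariate-adjusted estimator loses appreciably less,
reproducing the direction of the published adjusted-vs-unadjusted contrast.
The UE median in such cohorts is ~438 kcal/d even though intake truly
equals expenditure for everyone — unaccounted energy is mostly accounting
error.

The `examples/` directory holds one short narrative script per capability
(cohort simulation, baseline table, exclusion sweep, RQ sensitivity); each
prints its numbers with a line on what they mean. A thin CLI covers the
same pipeline: `exclusim full --seed 1 --out run/`.

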
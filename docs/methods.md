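# Methods

## Problem setting

Five published logistic models for *prevalent undiagnosed diabetes* —
the Cambridge, Kuwaiti, Omani, Rotterdam and simplified Finnish diabetes
risk models — are externally validated and then sequentially updated in
a new screening population. Each model has the form

    logit P(undiagnosed diabetes) = α + Σ_j β_j x_j

with design terms x_j derived from non-invasive fields (age, sex, BMI,
waist circumference, blood pressure, medication, smoking, family
history). The package evaluates each model as published ("Method 0"),
then applies an updating hierarchy of increasing invasiveness and
measures what each step buys in discrimination and calibration.

## The updating hierarchy

**Method 1 — intercept adjustment.** The intercept is shifted by the
prevalence correction factor `logit(observed prevalence) −
logit(mean predicted risk)`. This is a closed-form moment correction,
not a maximum-likelihood fit: after the shift, the training E/O ratio is
close to, but not exactly, 1 (the gap grows with the spread of the
linear predictor, since the logit of a mean is not the mean of logits).
Discrimination is untouched — a constant shift preserves ranks.

**Method 2 — logistic calibration.** Maximum-likelihood fit of
`outcome ~ a + b·LP`. The final model has intercept `a + b·α` and
coefficients `b·β_j`, so its linear predictor equals `a + b·LP`
exactly. The ML score equations force the training mean predicted risk
to equal the event rate, hence training E/O = 1 to numerical precision;
this is the analytic identity behind every "1.00" training calibration
cell in the result tables. A slope `b < 1` means the published
coefficients were too extreme for the new population.

**Method 3 — revision.** With the Method-2 fit held *fixed as an
offset*, each original term receives a free deviation coefficient γ_j
and is screened by a likelihood-ratio test (df = 1 per term; the result
tables report deviations for individual terms, so banded variables are
screened per band). Terms with p < α enter a joint ML refit
`outcome ~ α' + β'·LP + Σ γ_j x_j`, followed by parameterwise
shrinkage. If nothing is selected the result collapses to Method 2.
Because the offset is already the ML fit in the direction of LP, and
each x_j is a component of LP, these screening tests are conservative:
under the null their statistic is stochastically smaller than χ²(1).
That conservatism is what keeps the familywise false-selection rate of
the revision screen below 10% in the null simulations even with ~7
terms tested at α = 0.05.

**Method 4 — re-estimation.** Full ML refit of the original predictor
set in the training data, discarding the published coefficients, then
parameterwise shrinkage. Rank-deficient designs and (quasi-)complete
separation raise errors naming the offending terms; separation is
declared when an indicator coefficient exceeds 15 in absolute value.

**Method 5 — extension.** As Method 3, but the screened terms are *new*
candidate predictors (per model: the fields the original model does not
already use in any form). Multi-level categorical candidates (education,
smoking, drinking, the two family-history composites) are tested and
selected as a block with df = levels − 1. Selected terms are added to
the recalibrated model via a joint refit, then shrunk. Unlike Method 3,
these candidates are not components of LP, so each block's screening
test holds its nominal α level — and consequently the *familywise*
false-selection rate across ~6 independent blocks is ≈ 1 − 0.95⁶ ≈ 26%,
which is inherent to unadjusted per-candidate screening, not an
implementation artifact. The null-simulation test therefore bounds the
per-candidate rate (α plus Monte-Carlo slack), not the familywise rate.

**De novo development.** Backward stepwise logistic regression over the
full candidate pool (13 blocks), removing the block with the largest
LR p ≥ α until all survivors are significant, then parameterwise
shrinkage. Ties are broken by removing the block with the smaller
maximum |coefficient/SE|. Blocks that make the full starting model
inestimable through separation (in practice the 1.1%-prevalence
corticosteroid flag, which has zero-event cells in a sizable fraction of
722-record training sets) are dropped up front and recorded. If nothing
survives, an intercept-only model is returned with a warning. With 13
blocks kept at α = 0.05, the chance of retaining at least one spurious
block under a null outcome is ≈ 50% — backward selection controls
per-term, not familywise, error.

**Parameterwise shrinkage** (Methods 3–5 and the developed model). For
each of B = 200 seeded bootstrap resamples, the free model is refit; the
original-sample outcome is then regressed (logistic, free intercept) on
the per-term linear-predictor contributions `x_j·b_j^(boot)` of the
resample fit, and the per-term calibration slopes are averaged across
resamples to give the shrinkage factors, clipped to [0, 1.5]. Free
coefficients are multiplied by their factors, and the intercept is
re-estimated by ML with the shrunk terms as an offset — restoring
training E/O = 1. Resample fits that separate or degenerate are skipped
and counted; B < 50 triggers a warning. In the large-sample limit the
factors are ≈ 1; for a deliberately overfit model (120 records, 10 noise
terms) their mean drops well below 1.

## Performance metrics

* **C-statistic**: probability that a random event outranks a random
  non-event, ties counted ½; computed from midranks, with an asymptotic
  DeLong-type 95% CI from the per-group placement-value variances.
* **E/O ratio**: Σ predicted probabilities / Σ events. 95% CI from the
  Poisson log-scale approximation `ratio·exp(±1.96/√O)` — the closed
  form standardized-ratio reports conventionally print; exact
  chi-square Poisson bounds are available behind a flag.
* **Brier score**: mean squared prediction error.
* **Yates slope**: mean predicted risk in events minus non-events.
* **Calibration curves**: decile bins of predicted risk (quantile bins;
  merged with a warning when the score takes too few distinct values),
  mean predicted vs observed rate per bin against the identity line.

## Synthetic cohort generator

The generator emulates a community diabetes-screening survey of 1256
recruited participants, 173 of whom carry a prior diabetes diagnosis
(flagged, never given an OGTT outcome, excluded from analysis). Its
defaults are the study conditions: continuous marginals age 51.9 ± 14.9 y,
BMI 29.7 ± 7.0 kg/m², waist 95.8 ± 15.3 cm, SBP 124.3 ± 20.0 and DBP
76.0 ± 12.7 mmHg; binary prevalences (male 23.2%, antihypertensive use
34.5%, lipid-lowering 3.7%, corticosteroids 1.1%, mother/father/sister/
brother diabetes 11.5/5.6/9.5/6.2%, current alcohol 25.1%, current
smoking 40.0%); and per-field MCAR missingness (family-history flags
≈ 25% each, smoking 6.1%, other predictors 3%).

Design choices where the study reports no value:

* **Dependence structure.** Continuous fields use truncated-normal
  marginals (age 20–90, BMI 14–60, WC 50–160, SBP 80–220, DBP 40–130)
  coupled by a Gaussian copula with BMI–waist correlation 0.8 and
  SBP–DBP correlation 0.6 — plausible physiologic values, not survey
  estimates. All other pairs are independent.
* **Category splits.** Only the "current" fractions of smoking and
  alcohol and the high-school fraction of education are reported;
  ex-smoker and ex-drinker fractions are set to 15%, university
  education to 5.9%.
* **Outcome model.** Undiagnosed diabetes is drawn Bernoulli from a
  "true" risk model — by default the Omani model with its intercept
  recalibrated by monotone root-finding so the expected prevalence among
  analyzable records is 15% (the survey's undiagnosed prevalence). Any
  registry model, or a model with an explicit intercept and no
  recalibration, can be substituted for parameter-recovery simulations.
* **Missingness mechanism.** Fields are masked independently (MCAR).
  Real survey missingness is block-structured — the four family-history
  flags were plainly missing together — so independent masking at the
  same marginal rates yields ~77% of rows with at least one missing
  field, versus ~30% in the survey. Marginal rates, which drive the
  imputation step, are matched; the row-wise union is not.

What passing tests on this generator do **not** show: recovery of the
survey's data-dependent estimates (fitted correction factors, validated
C-statistics), which depend on the real cohort's joint covariate-outcome
distribution. The synthetic truth is a single known logistic model, so
model misspecification, measurement error and block missingness present
in real data are out of frame. The generator supports the *structural*
claims: flow counts, calibration identities, invariances, estimator
unbiasedness and test size/power.

## Numerical choices

* Logistic fits: IRLS (GLM with binomial family), log-likelihood
  tolerance 1e-8, max 100 iterations; offsets carry fixed components.
* Separation: indicator-term |coefficient| > 15 after convergence.
* LR statistics are clamped at 0; an alternative log-likelihood more
  than 1e-6 below its null raises.
* Intercept calibration root-finding: Brent on [−40, 40], xtol 1e-12;
  mean predicted risk matches the target to well below 1e-6.
* The train split holds `round(fraction·n)` records (1083 → 722/361 at
  2/3), drawn by seeded permutation without outcome stratification (the
  study's train/test prevalences differ, indicating no stratification).
* Mode-imputation ties break toward the reference level (never-smoker,
  never-drinker, primary education, flag = 0).
* All randomness flows through explicit integer seeds (cohort, split,
  missingness, bootstrap); experiment outputs embed the seeds and a
  config hash.

## Registry encoding decisions

* The Rotterdam age term ("per 5 years: 55 to >75", coefficient 0.190)
  is not defined by its source table; it is encoded as the count of
  completed 5-year increments above 55 (55–59 → 1, 60–64 → 2, …,
  capped at 5 from 75 up, 0 below 55).
* The Cambridge sex term is an indicator for female (−0.879) as
  printed; the steroid and antihypertensive terms are current-use
  indicators (ever-use is not distinguishable in the data model).
* Cambridge family-history categories are mutually exclusive ("parent
  or sibling, not both" vs "parent and sibling"); the Omani composite is
  the inclusive union. "Parent" means mother or father, "sibling"
  sister or brother.
* The Omani blood-pressure term is true if SBP ≥ 140 **or** DBP ≥ 90.
* Printed band edges like "25 ≤ BMI ≤ 27.49" are encoded as half-open
  intervals ([25, 27.5)), making each band family exclusive and
  exhaustive; the Finnish "BMI > 30" upper band is treated as ≥ 30 for
  the same reason.
* The Finnish "history of high blood glucose" term is fixed at zero for
  all participants (the survey could not measure it) and carried in the
  model as a declared fixed-zero term.

## Problem sizes in the test suite

The statistical property tests use simulation sizes chosen to make the
assertions sharp at modest cost: 50 seeds × 1256 records for prevalence
calibration; 100 cohorts of 5000 for recovery of a known intercept
shift (−1) with a doubled obesity coefficient; 200 cohorts of 1083 for
screening size control; 10 000–20 000 records for large-sample
shrinkage limits; bootstrap B = 50–100 inside tests versus the
default B = 200 in analyses.

## Known limitations

* The screening offset fixes both calibration parameters; freeing them
  per screen (a 3-parameter alternative) would make the Method-3 tests
  exact rather than conservative. The conservative variant mirrors the
  described procedure ("predictors individually added as an offset").
* Shrinkage factors for near-zero coefficients are noisy; the [0, 1.5]
  clip bounds the damage but individual factors should not be
  over-interpreted.
* E/O confidence intervals treat the expected count as fixed; for
  internally validated models this understates uncertainty.
* The generator draws family-history flags independently, so the
  implied prevalence of "parent and sibling" history (~2.6%) is lower
  than in populations where diabetes clusters in families.
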
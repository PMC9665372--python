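# Methods

## Model overview

`adjuvantsim` simulates the post-lobectomy course of patients aged 66–84
with locoregional (AJCC 8th edition stage IB–IIIA) non-small cell lung
cancer and major smoking-related comorbidities (COPD, CAD, mild/moderate
CHF), comparing two strategies: platinum-based adjuvant chemotherapy and
observation. It is a monthly-cycle individual-level state-transition
(micro)simulation. Each cycle a patient can die of lung cancer, die of
other causes, or survive; each survived cycle accrues one month of life
weighted by a utility in [0, 1]. Simulation continues until death or the
month the patient turns 100 (entry age is the midpoint of the age band, so
a 66–69 entrant is followed for up to 390 months).

Treatment enters through three mechanisms, all taken from randomized-trial
evidence:

* the monthly lung-cancer death probability in the chemotherapy arm is
  multiplied by the pooled-trial hazard ratio **0.83** (95% CI 0.76–0.90),
  uniformly across age/sex/stage (the pooled analysis found no
  interactions);
* the other-cause death probability is multiplied by **2.41** (95% CI
  1.64–3.55) during the first **6** cycles of the chemotherapy arm (early
  treatment toxicity), returning to background afterwards;
* non-fatal complications affect quality of life only: their mortality
  impact is already carried by the 6-month toxicity hazard ratio.

### Quality-of-life accounting

The per-cycle utility is

    u = max(0, baseline − d_CAD·CAD − d_COPD·COPD − d_CHF·CHF − c(m))

with additive comorbidity decrements d_CAD = 0.018, d_COPD = 0.021,
d_CHF = 0.069 (registry-linked health-survey estimates; additivity across
joint profiles is a package choice — the source publishes only per-condition
decrements). A major treatment complication subtracts
c(m) = 0.35 · (1 − m/6) for m = 0…5 months since the complication — a
linear return to baseline over six months. QALYs are the sum of monthly
utilities divided by 12. No discounting by default (a configurable annual
rate is exposed); no half-cycle correction (one full month of utility per
survived cycle, matching the model's stated accounting).

`baseline` utility is **0.80**. The source analyses publish only
*decrements*, not the anchor; 0.80 is a typical post-lobectomy utility in
the valuation literature. Decisions are threshold-based differences between
arms, so they are insensitive to the anchor; absolute QALY levels are not.

### Baseline mortality

The original analysis derived monthly transition probabilities from a
7,852-patient registry cohort; those stratum-level curves are unpublished.
The package therefore builds baseline (observation-arm) rates from a
documented parametric mechanism, fully overridable per stratum:

* lung-cancer death: constant monthly probability by stage —
  IB 0.004, IIA 0.006, IIB 0.009, IIIA 0.013 (≈ 79/70/58/46% 5-year
  cancer-specific survival, realistic for resected NSCLC);
* other-cause death: a reference curve for a 66–69 male with no
  comorbidity, 0.0017/month (≈ 2%/year) growing exponentially at 9%/year of
  attained age (a Gompertz-like force of mortality), multiplied by the
  published sub-hazard ratios of the patient's covariates (age band
  1.17/1.33/1.62, female 0.78, COPD 1.18, CAD 1.25, CHF 1.49).

Because the true baseline curves are unpublished, stratum-level headline
numbers (which strata cross the decision threshold) are reproduced
*qualitatively* — direction and monotonicity — not cell-for-cell.

Hazard ratios scale monthly probabilities multiplicatively (capped at 1) by
default; the exact discrete conversion 1 − (1 − p)^HR is available via
`hazard_scaling="exact"`. At monthly granularity with p ≤ 0.03 the two
differ by well under 1%.

### Complication models

Each of seven hospitalization-level complications (serious infection,
neutropenia, nausea/vomiting, anemia, thrombocytopenia, neuropathy, renal
failure) is an independent logistic model in age category, sex, COPD, CAD
and CHF level. Published non-significant cells enter as OR 1.0; the
published significant effects are female→nausea/vomiting 2.33,
COPD→infection 1.80, COPD→anemia 1.41, COPD→thrombocytopenia 2.39,
CHF→nausea/vomiting 5.58 and CHF→thrombocytopenia 3.46 (pooled over CHF
severity for those two outcomes), CHF mild→anemia 2.08, CHF severe→anemia
2.81. Baseline (reference-profile) risks are unpublished; the default
intercept is logit(0.05) per complication — hospitalization-level toxicity
of a platinum doublet at a few percent per category is a realistic order of
magnitude. Complications are drawn once per type at treatment start (the
course is short relative to the horizon and within-course timing is not
modelled); at most one 0.35 decrement applies regardless of how many types
occur. Observation-arm probabilities are the chemotherapy-arm probabilities
divided by the chemo-vs-observation complication relative risk from
randomized-trial data; that scalar is not published, so it is a required
configuration value with default **5.0** (serious adverse events were
severalfold more frequent under chemotherapy in the trial), applied to all
seven types and overridable.

Severe CHF appears in registry estimation (sub-HR 1.88) but is excluded
from simulated strata: such patients are not lobectomy candidates.

## Estimation path

**Fine-Gray regression.** Sub-hazard ratios of death from non-lung-cancer
causes are estimated by maximizing the IPCW-weighted subdistribution
partial likelihood: subjects failing from the competing cause remain in
later risk sets, weighted by the ratio of Kaplan-Meier censoring-survival
estimates G(t−)/G(T_i−) (left-continuous convention). Ties — ubiquitous on
a monthly clock — use the Breslow approximation. Newton-Raphson iterates to
a gradient max-norm of 1e-8 with step-halving; non-convergence raises,
never returns silently. Standard errors are inverse-information; CIs are
Wald on the log scale (the reference R implementation reports robust
sandwich SEs — point estimates agree to ~1e-7 on test fixtures, SEs to a
few percent). Implemented with prefix/suffix cumulative sums over the
sorted cohort, so a fit on 50,000 records with 8 covariates takes ~1 s.

**Cumulative incidence.** The Aalen-Johansen estimator on the monthly grid,
with the all-cause Kaplan-Meier as overall survival, implemented so that
CIF_nsclc + CIF_other + S = 1 holds exactly at every grid point. Monthly
transition probabilities are p_cause(m) = [F(m) − F(m−1)] / S(m−1), zero
where S(m−1) = 0; re-accumulating them through the cycle recursion
reproduces the input CIFs exactly.

Mortality models are always fitted on observation-only cohorts — the
treatment effect enters only through the trial hazard ratios, never through
baseline rates.

## Synthetic registry

The generator draws other-cause death times by exact inversion of the
proportional-subdistribution-hazards CIF

    F_other(t; x) = 1 − (1 − p·(1 − e^(−t/τ)))^exp(x'β),

so the Fine-Gray estimator is consistent for the configured β by
construction — the property the parameter-recovery tests rely on. Lung
cancer is the complementary cause (conditional exponential time, scale 40
months); censoring is independent geometric-by-month (0.005/month default);
continuous times are rounded up to whole months. Defaults: β = the
published sub-hazard ratios, p = 0.30, τ = 60 months. Covariates: uniform
age bands, balanced sex, 30% COPD, 30% CAD, 20%/10% mild/severe CHF,
uniform stage (the source cohorts' joint distribution is unpublished; these
are round realistic prevalences for a lobectomy registry). The generator
does **not** emulate calendar-time structure, covariate-dependent
censoring, or correlation between comorbidities — so passing recovery
tests show estimator correctness under the model's own assumptions, not
robustness to real-registry messiness.

## Trial suite

A trial simulates one stratum under both arms with **common random
numbers**: both arms consume identical uniform streams (draws are made for
dead patients too, keeping streams aligned), so with null effects the arms
are bitwise identical and ΔQALY = 0 exactly. This makes the 0.25-QALY
decision threshold stable at feasible cohort sizes: the paired ΔQALY
Monte-Carlo SE is ≈ 0.01 at 4,000 patients/arm (the grid driver's default;
the trial functions accept any n, and the effect-size re-estimation
checks use 100,000–200,000/arm). Adjuvant chemotherapy is recommended iff
ΔQALY ≥ 0.25 (inclusive — "at least" three quality-adjusted months). The
grid covers 4 ages × 2 sexes × 4 stages × 7 comorbidity profiles (none,
COPD, CAD, CHF, CAD+CHF, CAD+COPD, CHF+COPD — the source's listed pairs
contain a duplicate; the three distinct pairs are implemented) = 224
strata. One-way sensitivity reruns a stratum with the treatment HR at
{0.76, 0.90} and the toxicity HR at {1.64, 3.55}, all else (including
seeds) fixed; under common random numbers ΔQALY is monotone along each
sweep, so decision flips are single crossings.

Within a cycle, lung-cancer death takes precedence when both death draws
fire (a tie-break that keeps the realized cancer hazard exactly equal to
the configured probability; the other-cause hazard is attenuated by the
factor 1 − p_nsclc, below 1.5% at base case).

## Numerical and testing choices

* All randomness flows through `numpy` `SeedSequence`/`Generator`; every
  public entry point takes a seed or generator, and generation is
  bit-reproducible for a fixed seed.
* Single-replicate recovery tests at fixed seeds assert each coefficient
  within 3 SEs of truth (99.7% per coefficient): a joint 95%-CI assertion
  over eight coefficients would reject a correct estimator in about one
  run in three.
* The brute-force oracle for the Fine-Gray fit evaluates the exact
  subdistribution partial likelihood on a 1e-4 coefficient grid for tiny
  censoring-free datasets; the no-censoring case is also checked against a
  proportional-hazards fit with competing events held in all risk sets, and
  the censored case against `cmprsk::crr` in R.
* Problem sizes: recovery experiments use n = 50,000 registries (~1–2 s per
  fit); engine effect-size re-estimation uses 100,000–200,000 patients per
  arm (~5 s per check); the full 224-stratum grid at 4,000/arm runs in
  ~20 s.

## Known limitations

* Baseline monthly mortality and baseline utility are package defaults,
  not registry estimates; absolute QALY levels and the exact location of
  decision boundaries in the grid depend on them.
* Recurrence is not an explicit state (it is folded into the lung-cancer
  mortality rates), and cisplatin/carboplatin regimens are not
  distinguished — both matching the source model's scope.
* Complication types are drawn independently; comorbidity disutilities are
  additive; the ANITA-derived relative risk is a single scalar across
  complication types. Each is a documented assumption where the source is
  silent.
* No cost-effectiveness, no limited-resection patients, no targeted or
  immune therapies.
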
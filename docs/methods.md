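# Methods

This note documents the models, conventions and numerical choices behind
`metsdx`, and what its synthetic cohorts can and cannot establish.

## Data model and units

A cohort is one row per subject: sex, age (years), body weight (kg), height
(cm), waist and hip circumference (cm), systolic/diastolic blood pressure
(mmHg), fasting glucose, total cholesterol, HDL-C and triglycerides (all
mg/dL), plus three booleans (lipid-lowering treatment, treated hypertension,
diagnosed type-2 diabetes). Concentrations are stored in mg/dL — the units
laboratories report — and converted to mmol/L inside the index formulas with
the molar-mass factors 88.57 (triglycerides), 38.67 (cholesterol, total and
HDL) and 18.016 (glucose) mg/dL per mmol/L. These factors reproduce the
conventional paired thresholds (150 ↔ 1.7, 40 ↔ 1.0, 100 ↔ 5.6) at their
printed precision, and the conversion round-trips to < 1e-9 relative error.

Validation is advisory and never raises: each record is checked for strict
positivity of the continuous fields, the adult-inclusion bound age ≥ 18, and
plausibility guardrails (height 100–230 cm, WC/HC 40–250 cm). In non-strict
CSV reading, rows failing validation or missing a required field are
excluded and counted — the behaviour of observational cohorts that drop
subjects lacking the data needed for index computation — while strict mode
turns any such row into an error.

## Index formulas

- **BMI** = weight / height(m)².
- **BAI** = HC / height(m)^1.5 − 18. Anthropometry only; shares no
  component with the lipid/glucose/BP criteria except through whatever
  correlation hips have with the metabolic state.
- **LAP** = (WC − 65) × TG(mmol/L) for males, (WC − 58) × TG for females.
  The subtraction is applied *before* the product. The alternative literal
  reading WC − (anchor × TG) is numerically incompatible with published
  cohort-level LAP means (it gives ≈ 21 where product-form means are
  ≈ 98 at typical severely obese cohort averages), and with the index's
  originating definition. No option to switch is offered, to prevent silent
  misuse. A waist at or below the anchor makes LAP ≤ 0; such subjects
  cannot occur under a BMI > 35 inclusion criterion, so the panel flags the
  value as degenerate rather than failing.
- **CMI** = (TG/HDL-C, both mmol/L) / (WC/HC). Some literature divides the
  lipid ratio by waist-to-*height*; the waist-to-hip form implemented here
  is the definition this package targets, and with mmol/L lipid ratios it
  is consistent with published CMI magnitudes (≈ 1.3–1.9 in severe
  obesity). Computing the TG/HDL ratio in mg/dL instead would inflate CMI
  by the constant 88.57/38.67 ≈ 2.29; the mmol/L reading is adopted.

## MetS classification

Five binary criteria (waist ≥ 102/88 cm M/F; TG ≥ 150 mg/dL or lipid
treatment; HDL < 40/50 mg/dL M/F or lipid treatment; SBP ≥ 130 or DBP ≥ 85
mmHg or treated hypertension; glucose ≥ 100 mg/dL or diagnosed T2DM). The
`≥` thresholds are inclusive and the HDL threshold strictly `<`, exactly as
the criteria are conventionally printed. The single lipid-treatment flag
feeds both lipid criteria because treatment of "this lipid abnormality"
attaches to each; separate per-lipid flags are not modelled.

The default call is **MetS ⇔ ≥ 3 of 5 criteria**. The canonical IDF rule
(central obesity mandatory plus ≥ 2 of the remaining four) is available as
`idf_strict`; in severely obese cohorts the waist criterion is essentially
universal and the two rules coincide.

## ROC analysis

Candidate thresholds are the distinct observed scores plus ±∞ sentinels;
test-positive ⇔ score ≥ threshold; the direction higher-score ⇒ predicted
MetS is fixed (the indexes' cutoffs are lower bounds) and never auto-flipped.
The AUC is the Mann–Whitney probability with ties credited ½ (computed via
midranks), which is algebraically the trapezoidal area under the empirical
curve; the test suite holds the two routes to 1e-12 agreement.

The reported cutoff is the Youden-maximizing threshold itself (an observed
score value, not an inter-point midpoint). Ties in J are broken by the
higher specificity — in a screening context fewer false positives — then by
the higher threshold. The exhaustive-search equivalence of this selection is
tested on random instances.

The AUC confidence interval uses DeLong's nonparametric variance estimator
(placement values; normal quantile; clamped to [0, 1]) — deterministic and
standard where no CI method is otherwise specified. A seeded stratified
percentile bootstrap (default 2,000 resamples) is provided as a cross-check.
Likelihood ratios are computed from percent sensitivity/specificity;
division by zero yields an infinity marker (rendered as null in JSON, `inf`
in text).

Supporting statistics are delegated to scipy behind this module's surface:
pooled-variance Student's t (Welch optional), Pearson correlation.
Fisher's exact test is implemented directly in exact integer arithmetic
(two-sided p = sum of hypergeometric probabilities ≤ the observed table's,
with integer comparison of the unnormalized terms), so its agreement with
full enumeration carries no floating-point tie ambiguity.

Correlation strength bands partition |r| as < 0.10 negligible, [0.10, 0.40)
weak, [0.40, 0.70) moderate, [0.70, 0.90) strong, ≥ 0.90 very strong. The
conventional verbal bands leave gaps (0.10–0.11, 0.39–0.40, …); the
half-open intervals close them by assigning each boundary to the stronger
band. p-values are kept at full precision in JSON and binned for display
(ns, <0.05, <0.01, <0.001, <0.0001).

## Synthetic cohort generator

The generator emulates a severely obese adult inpatient cohort: n = 1912,
11.6% male, and per-sex means/SDs for eleven continuous variables (age,
height, BMI, WC, HC, SBP, DBP, glucose, total cholesterol, HDL-C, TG) taken
from published summary statistics of such a population. Triglycerides and
glucose are lognormal (right-skewed, as lipid panels are), parameterized to
hit the target mean/SD exactly; the other variables are truncated normals.

**Copula.** A latent multivariate normal with a configurable correlation
matrix is drawn per sex (Cholesky factor), and each coordinate is mapped
through its marginal's quantile function. This preserves every marginal
exactly regardless of the correlation structure. Bounded variables use
truncated-normal marginals whose *parent* parameters are moment-matched
(2-equation root solve on the truncated mean/SD) so that the configured
mean/SD are the moments of the truncated distribution. This is why the
binding BMI > 35 inclusion bound neither shifts the realized BMI moments
nor leaks selection bias into correlated variables, and produces no point
mass at the boundary — a row-rejection scheme would do all three.

**Derived fields.** Body weight is BMI × height(m)² exactly per subject
(generating height and BMI and deriving weight keeps the inclusion
criterion and the near-equal BMI across sexes easy to honour). Blood
pressures are rounded to the nearest 5 mmHg, as sphygmomanometer protocols
round; this matters for the BP criterion, since SBP ≥ 130 after rounding
corresponds to a raw 127.5.

**Correlation defaults.** Cohort summary tables publish no covariances, so
the default matrix is a declared assumption: moderate positives among
adiposity measures (BMI–WC–HC 0.55–0.65), SBP–DBP 0.6, weak metabolic
couplings (TG–glucose 0.2, TG–HDL −0.3, age–SBP 0.3), near-zero elsewhere.
It ships in the config file; every entry is user-overridable, and
positive-definiteness is validated.

**Prevalence calibration.** A single multiplier in [0, 1] scales the latent
correlations between variables of *different* criteria (SBP–DBP, within one
criterion, is untouched), and bisection on the simulated prevalence at
n = 20,000 (common random numbers across evaluations) stops within ±2
percentage points of the target. Under the default marginals with all
treatment flags at 0 the attainable prevalence spans only ≈ 58.7–60.4%
(less criterion correlation means more subjects with ≥ 3 of 5), so the
default 62.3% target is met only at the tolerance edge, at the
independence end of the range; `calibrated_default_config` therefore falls
back to the closest endpoint with a logged notice when a particular seed's
draw lands just outside tolerance. Treated-comorbidity flags, which would
raise the BP and glucose criterion frequencies toward published levels, are
deliberately left at 0 because no comorbidity prevalences are available for
this population; the flags exist so the classifier's override logic is
exercisable.

**What the synthetic cohort shows — and what it does not.** It reproduces
the marginal means/SDs, the lipid skew, the sex imbalance, the severe-
obesity truncation, and the qualitative discrimination ordering: indexes
embedding waist and lipids (LAP, CMI) track the MetS criteria while the
anthropometry-only BAI stays at the chance diagonal (AUC gaps ≥ 0.15 on the
default calibrated cohort). It does **not** reproduce any real cohort's
joint distribution, so exact AUCs, cutoffs and correlation tables from real
data are out of reach by construction; passing tests establish the
correctness of the machinery and the qualitative structure, not clinical
performance.

## Problem sizes and determinism

Marginal-recovery checks run at n = 20,000 (≈ 2,300 males at the default
sex mix), where 3-SE mean recovery and 5% SD recovery are sharp but
attainable; interval-coverage checks use 1,000 replicates of n = 100;
ROC-oracle equivalences use 1,000 random instances of n ≤ 30; the
Fisher-vs-enumeration check covers every 2×2 table with total ≤ 40. Every
stochastic component takes an explicit seed (`numpy.random.default_rng`);
there is no hidden global randomness, and a report regenerated from the
same inputs is byte-identical JSON.

## Known limitations

- The generator's lognormal/truncated-normal families are a modelling
  choice; real lab distributions have heavier tails and measurement
  heaping (e.g. glucose) that are not emulated.
- Treatment flags default to 0, so criterion frequencies for BP and
  glucose sit below typically published levels (which fold in treated
  disease), capping the realizable MetS prevalence near 61%.
- Age enters the criteria only through correlations; no explicit
  age-dependence of the marginals is modelled beyond the per-sex means.
- The DeLong CI is asymptotic; for very small strata (< 2 per class) the
  pipeline skips the stratum with a logged notice rather than reporting an
  unstable interval.
- Only the waist-to-hip CMI and the product-form LAP are offered; variant
  indexes (VAI, TyG, ABSI, waist-to-height CMI) are out of scope.
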
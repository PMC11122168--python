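# metsdx

Adiposity–lipid screening indexes, rule-based metabolic-syndrome (MetS)
classification, and ROC diagnostic-accuracy analysis for adult obesity
cohorts — as a tested, reusable Python library.

## Who this is for

Clinical epidemiologists and biostatisticians evaluating cheap bedside
surrogates for metabolic dysfunction in cohorts of adults with obesity.
The central question the package answers: *how well does an index computed
from a tape measure and a routine lipid panel identify the patients who
meet the metabolic-syndrome criteria?*

## The science in brief

**Indexes** (per subject; lipids in mmol/L inside the formulas):

- BMI = weight (kg) / height (m)²
- BAI = HC / height (m)^1.5 − 18 — hip circumference (HC) and height only
- LAP = (WC − 65) × TG for males, (WC − 58) × TG for females — waist
  circumference (WC) plus fasting triglycerides (TG)
- CMI = (TG / HDL-C) / (WC / HC) — adds the atherogenic lipid ratio

**MetS classification** follows the IDF component thresholds: abdominal
obesity (WC ≥ 102/88 cm, M/F), TG ≥ 150 mg/dL, HDL-C < 40/50 mg/dL (M/F),
blood pressure ≥ 130/85 mmHg, fasting glucose ≥ 100 mg/dL, each also
satisfiable by the corresponding treatment/diagnosis flag; MetS is called
when ≥ 3 of the 5 criteria are met (a mandatory-central-obesity variant is
available via `idf_strict`).

**Diagnostic accuracy**: each index is scored against the MetS label with
an empirical ROC curve (test-positive ⇔ score ≥ threshold), the
Mann–Whitney AUC with a DeLong 95% CI, the Youden-optimal cutoff
(J = sensitivity + specificity − 1), and likelihood ratios
LR+ = sens/(1 − spec), LR− = (1 − sens)/spec — overall and stratified by
sex and by age (≤ 50 vs > 50 years).

**Synthetic cohorts**: because patient-level data of this kind are rarely
shared, a Gaussian-copula generator draws reproducible two-sex cohorts
with configurable per-sex marginal means/SDs (defaults describe a severely
obese adult inpatient population, 88.4% female), right-skewed lognormal
triglycerides/glucose, a user-editable latent correlation matrix, and a
calibration routine that tunes inter-criterion correlations toward a
target MetS prevalence.

## Worked example

```python
from metsdx import SubjectRecord, compute_panel, evaluate_criteria

record = SubjectRecord(
    id="p1", sex="male", age=48, body_weight=126.9, height=172.0,
    waist=131.5, hip=130.1, sbp=130, dbp=80, glucose=101,
    total_chol=191, hdl=41.6, triglycerides=164.7)

panel = compute_panel(record)
print(f"BMI={panel.bmi:.1f} BAI={panel.bai:.1f} "
      f"LAP={panel.lap:.1f} CMI={panel.cmi:.2f}")
assessment = evaluate_criteria(record)
print(assessment.criteria_count, assessment.mets)
```

prints

```
BMI=42.9 BAI=39.7 LAP=123.7 CMI=1.71
5 True
```

— a severely obese male (BMI 42.9) whose waist and lipid profile put LAP
well above the ~90 screening range and who meets all five MetS criteria.

The `examples/` directory holds one short narrative script per capability
(indexes, classification, ROC/Youden, synthetic cohorts, full pipeline),
each printing the numbers it computes and what they mean. The same
workflow is available from the shell:

```bash
metsdx demo --seed 7 --out-dir demo_out     # simulate + analyze end to end
metsdx simulate --seed 1 --n 500 --out cohort.csv
metsdx analyze cohort.csv --out-dir out --format text --format csv_bundle
```

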
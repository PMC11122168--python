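"""Classify metabolic syndrome for a small cohort with the IDF-style rule.

Shows the five criterion booleans, the treatment overrides, and the cohort
prevalence summary.
"""
from metsdx import CohortTable, SubjectRecord, classify_cohort, evaluate_criteria

subjects = [
    # three criteria at their boundaries: abdominal + TG + HDL -> MetS+
    SubjectRecord(id="boundary", sex="male", age=50, body_weight=120,
                  height=175, waist=102, hip=120, sbp=129, dbp=84,
                  glucose=99, total_chol=190, hdl=39.9, triglycerides=150),
    # labs are clean but lipid treatment satisfies both lipid criteria
    SubjectRecord(id="treated", sex="female", age=60, body_weight=105,
                  height=160, waist=95, hip=125, sbp=120, dbp=75,
                  glucose=90, total_chol=180, hdl=60, triglycerides=90,
                  lipid_treated=True),
    # abdominal obesity only -> MetS-
    SubjectRecord(id="central-only", sex="female", age=35, body_weight=110,
                  height=162, waist=120, hip=130, sbp=118, dbp=72,
                  glucose=88, total_chol=185, hdl=58, triglycerides=95),
]

for subject in subjects:
    a = evaluate_criteria(subject)
    met = [name for name in ("abdominal_obesity", "high_tg", "low_hdl",
                             "high_bp", "high_glucose") if getattr(a, name)]
    print(f"{subject.id:>13}: {a.criteria_count}/5 criteria ({', '.join(met) or 'none'})"
          f" -> MetS {'POSITIVE' if a.mets else 'negative'}")

_, summary = classify_cohort(CohortTable(records=subjects))
print(f"\ncohort prevalence: {summary['mets_count']}/{summary['n']} "
      f"= {summary['prevalence_pct']:.1f}%  (MetS means >= 3 of 5 criteria)")
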
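"""The whole study workflow in one pass: simulate the default calibrated
cohort, compute indexes, classify MetS, and compare the three indexes as
MetS predictors across strata.

Equivalent to the CLI one-liner ``metsdx demo --seed 7``.
"""
from metsdx import run_full_analysis, simulate_cohort
from metsdx.pipeline import report_to_text
from metsdx.simulate import calibrated_default_config

config = calibrated_default_config(seed=7)
cohort, sim_report = simulate_cohort(config, seed=7)
report = run_full_analysis(cohort, seed=7)

print(report_to_text(report))
pop = report["roc"]["population"]
gap_lap = pop["lap"]["auc"] - pop["bai"]["auc"]
gap_cmi = pop["cmi"]["auc"] - pop["bai"]["auc"]
print(f"LAP and CMI out-discriminate BAI by {gap_lap:.2f} and {gap_cmi:.2f} AUC:")
print("indexes that embed waist and lipids track the MetS criteria, while the")
print("anthropometry-only BAI hovers at the chance diagonal (AUC ~ 0.5).")
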
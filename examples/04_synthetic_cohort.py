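"""Generate a reproducible synthetic obese-adult cohort and check what the
Gaussian-copula generator delivers: exact marginal targets, right-skewed
lipids, and the configured correlation structure.
"""
import numpy as np
from scipy import stats

from metsdx import default_config, simulate_cohort

config = default_config()
config.n = 5000
cohort, report = simulate_cohort(config, seed=7)
df = cohort.to_frame()

females = df[df["sex"] == "female"]
target = config.marginals["female"]["triglycerides"]
print(f"cohort: {report.n} subjects, {len(females)} female, seed {report.seed}")
print(f"female TG: realized {females['triglycerides'].mean():.1f} "
      f"+/- {females['triglycerides'].std(ddof=1):.1f} mg/dL "
      f"(target {target.mean} +/- {target.sd}); "
      f"skewness {stats.skew(females['triglycerides']):.2f} (> 0: right tail)")

bmi = df["body_weight"] / (df["height"] / 100) ** 2
print(f"BMI range {bmi.min():.1f}-{bmi.max():.1f} kg/m^2 "
      "(inclusion bound > 35 holds with no pile-up at the boundary)")
print(f"waist-TG correlation (females): "
      f"{np.corrcoef(females['waist'], females['triglycerides'])[0, 1]:+.2f} "
      "(configured latent 0.20)")
print(f"realized MetS prevalence: {report.prevalence_pct:.1f}%")
print()
print("Re-running with the same seed reproduces this cohort byte for byte;")
print("changing the correlation matrix changes the joint structure but never")
print("the marginal means/SDs.")
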
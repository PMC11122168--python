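"""Compute the four adiposity/lipid indexes for a single subject.

The record mimics a typical male patient from a severe-obesity cohort;
lipids are given in mg/dL and converted to mmol/L internally.
"""
from metsdx import SubjectRecord, compute_panel

record = SubjectRecord(
    id="example-male", sex="male", age=48, body_weight=126.9, height=172.0,
    waist=131.5, hip=130.1, sbp=130, dbp=80, glucose=101,
    total_chol=191, hdl=41.6, triglycerides=164.7,
)

panel = compute_panel(record)
print(f"BMI = {panel.bmi:.1f} kg/m^2   (weight / height^2)")
print(f"BAI = {panel.bai:.1f}          (hip / height^1.5 - 18; anthropometry only)")
print(f"LAP = {panel.lap:.1f}         ((waist - 65) x TG mmol/L; lipid overaccumulation)")
print(f"CMI = {panel.cmi:.2f}          ((TG/HDL) / (waist/hip); adiposity + dyslipidemia)")
print()
print("A LAP above ~90 or a CMI above ~1.2 typically lands in the range that")
print("flags metabolic syndrome in severely obese adults; a BAI near 40 says")
print("little, since it ignores lipids entirely.")
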
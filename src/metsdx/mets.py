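"""Rule-based metabolic-syndrome (MetS) classification on IDF component thresholds.

Five binary criteria are evaluated per subject:

1. abdominal obesity — waist >= 102 cm (males) / >= 88 cm (females)
2. elevated triglycerides — TG >= 150 mg/dL, or lipid-lowering treatment
3. reduced HDL-C — HDL < 40 mg/dL (males) / < 50 mg/dL (females), or
   lipid-lowering treatment
4. raised blood pressure — SBP >= 130 or DBP >= 85 mmHg, or treated
   hypertension
5. raised fasting glucose — glucose >= 100 mg/dL, or diagnosed type 2
   diabetes

The default call is MetS-positive when at least three of the five criteria
are met.  The canonical IDF variant — central obesity mandatory plus at
least two of the remaining four — is available via ``idf_strict=True``; in
severely obese cohorts (where the waist criterion is essentially universal)
the two rules coincide.

All ``>=`` thresholds are inclusive; the HDL threshold is a strict ``<``.
The lipid-treatment flag satisfies both lipid criteria, because treatment
for "this lipid abnormality" is attached to each.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MALE, FEMALE, CohortTable, SubjectRecord

#: IDF component thresholds (mg/dL for analytes, cm for waist, mmHg for BP).
WAIST_THRESHOLD = {MALE: 102.0, FEMALE: 88.0}
TG_THRESHOLD = 150.0
HDL_THRESHOLD = {MALE: 40.0, FEMALE: 50.0}
SBP_THRESHOLD = 130.0
DBP_THRESHOLD = 85.0
GLUCOSE_THRESHOLD = 100.0

CRITERIA = ("abdominal_obesity", "high_tg", "low_hdl", "high_bp", "high_glucose")


@dataclass(frozen=True)
class MetSAssessment:
    """The five criterion booleans, their count, and the MetS call."""

    abdominal_obesity: bool
    high_tg: bool
    low_hdl: bool
    high_bp: bool
    high_glucose: bool
    criteria_count: int
    mets: bool


def evaluate_criteria(record: SubjectRecord, idf_strict: bool = False) -> MetSAssessment:
    """Evaluate the five MetS criteria for one subject.

    Raises ``ValueError`` if a required field is missing (NaN) or the sex is
    unknown.
    """
    if record.sex not in WAIST_THRESHOLD:
        raise ValueError(f"unknown sex {record.sex!r}")
    required = ("waist", "triglycerides", "hdl", "sbp", "dbp", "glucose")
    for name in required:
        value = getattr(record, name)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValueError(f"missing required field {name!r}")

    abdominal = record.waist >= WAIST_THRESHOLD[record.sex]
    high_tg = record.triglycerides >= TG_THRESHOLD or record.lipid_treated
    low_hdl = record.hdl < HDL_THRESHOLD[record.sex] or record.lipid_treated
    high_bp = record.sbp >= SBP_THRESHOLD or record.dbp >= DBP_THRESHOLD or record.htn_treated
    high_glucose = record.glucose >= GLUCOSE_THRESHOLD or record.t2dm_diagnosed

    flags = (abdominal, high_tg, low_hdl, high_bp, high_glucose)
    count = int(sum(flags))
    if idf_strict:
        mets = abdominal and (count - int(abdominal)) >= 2
    else:
        mets = count >= 3
    return MetSAssessment(*[bool(f) for f in flags], criteria_count=count, mets=bool(mets))


def assessment_frame(df: pd.DataFrame, idf_strict: bool = False) -> pd.DataFrame:
    """Vectorized criteria evaluation for a cohort frame.

    Returns a frame with the five criterion booleans, ``criteria_count`` and
    ``mets``, aligned with the input rows.
    """
    male = df["sex"].to_numpy() == MALE
    waist_thr = np.where(male, WAIST_THRESHOLD[MALE], WAIST_THRESHOLD[FEMALE])
    hdl_thr = np.where(male, HDL_THRESHOLD[MALE], HDL_THRESHOLD[FEMALE])
    lipid = df["lipid_treated"].to_numpy(bool)
    out = pd.DataFrame({
        "abdominal_obesity": df["waist"].to_numpy(float) >= waist_thr,
        "high_tg": (df["triglycerides"].to_numpy(float) >= TG_THRESHOLD) | lipid,
        "low_hdl": (df["hdl"].to_numpy(float) < hdl_thr) | lipid,
        "high_bp": (df["sbp"].to_numpy(float) >= SBP_THRESHOLD)
                   | (df["dbp"].to_numpy(float) >= DBP_THRESHOLD)
                   | df["htn_treated"].to_numpy(bool),
        "high_glucose": (df["glucose"].to_numpy(float) >= GLUCOSE_THRESHOLD)
                        | df["t2dm_diagnosed"].to_numpy(bool),
    }, index=df.index)
    out["criteria_count"] = out[list(CRITERIA)].sum(axis=1).astype(int)
    if idf_strict:
        out["mets"] = out["abdominal_obesity"] & (
            (out["criteria_count"] - out["abdominal_obesity"].astype(int)) >= 2)
    else:
        out["mets"] = out["criteria_count"] >= 3
    return out


def percent(count: int, total: int) -> float:
    """A share expressed in percent (100 * count / total)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * count / total


def classify_cohort(cohort: CohortTable | pd.DataFrame,
                    idf_strict: bool = False) -> tuple[pd.DataFrame, dict]:
    """Classify every subject and summarize prevalence.

    Returns ``(assessments, summary)`` where ``assessments`` is the
    per-subject criterion frame and ``summary`` holds the cohort size, the
    MetS-positive count, the prevalence in percent, the per-criterion
    frequencies (count and percent) and the criteria-count histogram.
    """
    df = cohort.to_frame() if isinstance(cohort, CohortTable) else cohort
    if len(df) == 0:
        raise ValueError("empty cohort")
    assess = assessment_frame(df, idf_strict=idf_strict)
    n = len(assess)
    k = int(assess["mets"].sum())
    hist = assess["criteria_count"].value_counts().sort_index()
    summary = {
        "n": n,
        "mets_count": k,
        "prevalence_pct": percent(k, n),
        "criteria": {
            c: {"count": int(assess[c].sum()), "pct": percent(int(assess[c].sum()), n)}
            for c in CRITERIA
        },
        "criteria_count_mean": float(assess["criteria_count"].mean()),
        "criteria_count_histogram": {int(i): int(v) for i, v in hist.items()},
    }
    return assess, summary
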
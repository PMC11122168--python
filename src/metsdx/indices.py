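"""Per-subject adiposity and lipid indexes: BMI, BAI, LAP, CMI.

All four are cheap bedside surrogates for adiposity / lipid over-accumulation:

* BMI  = weight (kg) / height (m)^2
* BAI  = hip (cm) / height (m)^1.5 - 18          (anthropometry only)
* LAP  = (waist (cm) - anchor) * TG (mmol/L)     (anchor 65 males, 58 females)
* CMI  = (TG / HDL-C, both mmol/L) / (waist / hip)

Triglycerides and HDL enter LAP/CMI in mmol/L; the cohort data model stores
them in mg/dL and this module converts internally, so callers never
pre-convert.

The LAP anchors are the sex-specific minimum waist circumferences of the
index's originating population; a waist at or below the anchor makes LAP
non-positive, which cannot arise in severely obese cohorts but is tolerated
(flagged, not fatal) for general use.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (MALE, FEMALE, MG_PER_MMOL, CohortTable, SubjectRecord,
                     convert_units, validate_record)

#: Sex-specific waist anchor (cm) in the LAP formula.
LAP_ANCHOR = {MALE: 65.0, FEMALE: 58.0}


@dataclass(frozen=True)
class IndexPanel:
    """The four computed indexes for one subject.

    ``lap_degenerate`` marks subjects whose waist does not exceed the LAP
    anchor, for whom LAP <= 0 and is not interpretable.
    """

    bmi: float
    bai: float
    lap: float
    cmi: float
    lap_degenerate: bool = False


def _require_positive(**kwargs: object) -> None:
    for name, value in kwargs.items():
        arr = np.asarray(value, dtype=float)
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(f"{name} must be strictly positive and finite")


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, weight (kg) over squared height (m)."""
    _require_positive(weight=weight, height=height)
    h_m = np.asarray(height, dtype=float) / 100.0
    return np.asarray(weight, dtype=float) / h_m**2


def compute_bai(hip: float, height: float) -> float:
    """Body adiposity index: hip (cm) / height (m)^1.5 - 18."""
    _require_positive(hip=hip, height=height)
    h_m = np.asarray(height, dtype=float) / 100.0
    return np.asarray(hip, dtype=float) / h_m**1.5 - 18.0


def compute_lap(waist: float, tg: float, sex: str) -> float:
    """Lipid accumulation product: (waist - anchor) * triglycerides (mmol/L).

    ``sex`` selects the anchor (65 cm males, 58 cm females).  The result is
    non-positive when waist <= anchor; see :func:`compute_panel` for the
    degeneracy flag.
    """
    if sex not in LAP_ANCHOR:
        raise ValueError(f"unknown sex {sex!r}; expected 'male' or 'female'")
    _require_positive(waist=waist, tg=tg)
    return (np.asarray(waist, dtype=float) - LAP_ANCHOR[sex]) * np.asarray(tg, dtype=float)


def compute_cmi(tg: float, hdl: float, waist: float, hip: float) -> float:
    """Cardiometabolic index: (TG/HDL-C, mmol/L) divided by (waist/hip)."""
    _require_positive(tg=tg, hdl=hdl, waist=waist, hip=hip)
    tg = np.asarray(tg, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    waist = np.asarray(waist, dtype=float)
    hip = np.asarray(hip, dtype=float)
    return (tg / hdl) / (waist / hip)


def compute_panel(record: SubjectRecord) -> IndexPanel:
    """Compute all four indexes for one validated record.

    Lipids are converted mg/dL -> mmol/L internally; the caller supplies the
    record in laboratory units.  Raises ``ValueError`` if the record fails
    validation.
    """
    issues = validate_record(record)
    if issues:
        raise ValueError("record fails validation: " + "; ".join(str(i) for i in issues))
    tg_mmol = convert_units(record.triglycerides, "triglycerides", "mgdl_to_mmol")
    hdl_mmol = convert_units(record.hdl, "cholesterol", "mgdl_to_mmol")
    lap = compute_lap(record.waist, tg_mmol, record.sex)
    return IndexPanel(
        bmi=float(compute_bmi(record.body_weight, record.height)),
        bai=float(compute_bai(record.hip, record.height)),
        lap=float(lap),
        cmi=float(compute_cmi(tg_mmol, hdl_mmol, record.waist, record.hip)),
        lap_degenerate=bool(record.waist <= LAP_ANCHOR[record.sex]),
    )


def panel_frame(cohort: CohortTable | pd.DataFrame) -> pd.DataFrame:
    """Vectorized panel for a whole cohort: id + bmi, bai, lap, cmi columns."""
    df = cohort.to_frame() if isinstance(cohort, CohortTable) else cohort
    tg = df["triglycerides"].to_numpy(float) / MG_PER_MMOL["triglycerides"]
    hdl = df["hdl"].to_numpy(float) / MG_PER_MMOL["cholesterol"]
    waist = df["waist"].to_numpy(float)
    hip = df["hip"].to_numpy(float)
    h_m = df["height"].to_numpy(float) / 100.0
    anchor = np.where(df["sex"].to_numpy() == MALE, LAP_ANCHOR[MALE], LAP_ANCHOR[FEMALE])
    out = pd.DataFrame({
        "id": df["id"].astype(str),
        "bmi": df["body_weight"].to_numpy(float) / h_m**2,
        "bai": hip / h_m**1.5 - 18.0,
        "lap": (waist - anchor) * tg,
        "cmi": (tg / hdl) / (waist / hip),
        "lap_degenerate": waist <= anchor,
    })
    return out


def write_panels(cohort: CohortTable, path: str) -> None:
    """Export the per-subject index panel as CSV (6 significant digits)."""
    panel_frame(cohort).drop(columns="lap_degenerate").to_csv(
        path, index=False, float_format="%.6g")
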
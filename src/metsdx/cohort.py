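"""Subject-level cohort data model, CSV input/output, and laboratory unit conversion.

A cohort is a flat table, one row per subject, carrying the anthropometric
measurements (weight, height, waist and hip circumference), blood pressure,
fasting laboratory values (glucose, total and HDL cholesterol, triglycerides,
all in mg/dL), and three optional treatment/diagnosis flags used by the
metabolic-syndrome criteria.  The accepted on-disk form is a plain CSV with a
single header row, comma separator, period decimal mark, UTF-8 encoding; sex
is coded ``M``/``F`` and booleans ``0``/``1``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MALE = "male"
FEMALE = "female"

#: Continuous measurement columns, all required for index computation and
#: MetS classification.  Units: age years; weight kg; lengths cm; pressures
#: mmHg; analytes mg/dL.
NUMERIC_FIELDS: tuple[str, ...] = (
    "age", "body_weight", "height", "waist", "hip",
    "sbp", "dbp", "glucose", "total_chol", "hdl", "triglycerides",
)

#: Optional boolean columns; absent columns default to False (logged once).
FLAG_FIELDS: tuple[str, ...] = ("lipid_treated", "htn_treated", "t2dm_diagnosed")

REQUIRED_COLUMNS: tuple[str, ...] = ("id", "sex") + NUMERIC_FIELDS
ALL_COLUMNS: tuple[str, ...] = REQUIRED_COLUMNS + FLAG_FIELDS

#: Inclusion criterion: adults only.
MIN_AGE = 18.0

#: Plausibility guardrails (cm) for gross data-entry errors.
PLAUSIBILITY_BOUNDS: dict[str, tuple[float, float]] = {
    "height": (100.0, 230.0),
    "waist": (40.0, 250.0),
    "hip": (40.0, 250.0),
}

#: mg/dL per mmol/L, from the analytes' molar masses.
MG_PER_MMOL: dict[str, float] = {
    "triglycerides": 88.57,
    "cholesterol": 38.67,
    "glucose": 18.016,
}


@dataclass
class SubjectRecord:
    """One subject's measurements.

    ``sex`` is ``"male"`` or ``"female"``.  Lipid and glucose concentrations
    are stored in mg/dL (the units of the source laboratory); downstream
    index computation converts to mmol/L internally.
    """

    id: str
    sex: str
    age: float
    body_weight: float
    height: float
    waist: float
    hip: float
    sbp: float
    dbp: float
    glucose: float
    total_chol: float
    hdl: float
    triglycerides: float
    lipid_treated: bool = False
    htn_treated: bool = False
    t2dm_diagnosed: bool = False


@dataclass(frozen=True)
class ValidationIssue:
    field: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.message}"


@dataclass
class CohortTable:
    """An ordered collection of validated subject records.

    ``excluded_count`` records how many input rows were dropped (missing or
    invalid required fields) when the table was read in non-strict mode, so
    that retained + excluded always equals the input row count.
    """

    records: list[SubjectRecord] = field(default_factory=list)
    excluded_count: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SubjectRecord:
        return self.records[i]

    def to_frame(self) -> pd.DataFrame:
        """Return the cohort as a DataFrame with canonical column order."""
        data = {c: [getattr(r, c) for r in self.records] for c in ALL_COLUMNS}
        df = pd.DataFrame(data, columns=list(ALL_COLUMNS))
        for c in FLAG_FIELDS:
            df[c] = df[c].astype(bool)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, excluded_count: int = 0) -> "CohortTable":
        records = [
            SubjectRecord(**{c: row[c] for c in ALL_COLUMNS}) for row in
            df[list(ALL_COLUMNS)].to_dict("records")
        ]
        for r in records:
            r.id = str(r.id)
            r.lipid_treated = bool(r.lipid_treated)
            r.htn_treated = bool(r.htn_treated)
            r.t2dm_diagnosed = bool(r.t2dm_diagnosed)
        return cls(records=records, excluded_count=excluded_count)


def _parse_sex(value: object) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip().lower()
    if s in ("m", "male"):
        return MALE
    if s in ("f", "female"):
        return FEMALE
    return None


def _parse_flag(value: object) -> bool | None:
    if value is None:
        return None
    s = str(value).strip().lower()
    if s in ("", "nan"):
        return None
    if s in ("1", "true", "t", "yes", "y"):
        return True
    if s in ("0", "false", "f", "no", "n"):
        return False
    return None


def validate_record(record: SubjectRecord) -> list[ValidationIssue]:
    """Check a record against the data-model invariants.

    Returns an empty list iff the record is valid.  Never raises: validation
    reports problems, it does not enforce them.
    """
    issues: list[ValidationIssue] = []
    if record.sex not in (MALE, FEMALE):
        issues.append(ValidationIssue("sex", "category",
                                      f"sex must be male/female, got {record.sex!r}"))
    for name in NUMERIC_FIELDS:
        value = getattr(record, name)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            issues.append(ValidationIssue(name, "missing", f"{name} is missing"))
            continue
        if value <= 0:
            issues.append(ValidationIssue(name, "positivity",
                                          f"{name} must be strictly positive, got {value}"))
    age = record.age
    if age is not None and not (isinstance(age, float) and np.isnan(age)) and 0 < age < MIN_AGE:
        issues.append(ValidationIssue("age", "inclusion",
                                      f"age must be >= {MIN_AGE:g} years, got {age}"))
    for name, (lo, hi) in PLAUSIBILITY_BOUNDS.items():
        value = getattr(record, name)
        if value is not None and not (isinstance(value, float) and np.isnan(value)):
            if value > 0 and not (lo <= value <= hi):
                issues.append(ValidationIssue(
                    name, "plausibility",
                    f"{name} = {value} outside plausible range [{lo:g}, {hi:g}] cm"))
    return issues


def convert_units(value: float, analyte: str, direction: str) -> float:
    """Convert a lab concentration between mg/dL and mmol/L.

    ``analyte`` is one of ``triglycerides``, ``cholesterol`` (total or HDL),
    ``glucose``; ``direction`` is ``mgdl_to_mmol`` or ``mmol_to_mgdl``.  The
    conversion is a pure multiplicative factor, so the round trip is the
    identity to floating precision.
    """
    key = str(analyte).lower()
    if key in ("hdl", "total_chol", "total cholesterol", "hdl-c", "t-c"):
        key = "cholesterol"
    if key not in MG_PER_MMOL:
        raise ValueError(f"unknown analyte {analyte!r}; expected one of "
                         f"{sorted(MG_PER_MMOL)}")
    factor = MG_PER_MMOL[key]
    if direction == "mgdl_to_mmol":
        return value / factor
    if direction == "mmol_to_mgdl":
        return value * factor
    raise ValueError(f"unknown direction {direction!r}")


def load_column_map(path: str | Path) -> dict[str, str]:
    """Read a flat ``canonical = csv_header`` mapping file (# comments allowed)."""
    mapping: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'canonical = header'")
        key, val = (part.strip() for part in line.split("=", 1))
        if key.lower() not in ALL_COLUMNS:
            raise ValueError(f"{path}:{lineno}: unknown canonical column {key!r}")
        mapping[key.lower()] = val
    return mapping


def read_cohort(path: str | Path, strict: bool = False,
                column_map: Mapping[str, str] | None = None) -> CohortTable:
    """Read a cohort CSV, validating each row.

    In non-strict mode, rows that are missing a required field or fail
    validation are excluded and counted (``excluded_count``), mirroring how
    observational cohorts drop subjects lacking the data needed for index
    computation.  In strict mode any such row raises ``ValueError``.
    Header matching is case-insensitive; missing flag columns default to
    False with a logged warning.
    """
    try:
        raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file (no header row)") from exc
    except OSError as exc:
        raise ValueError(f"{path}: unreadable ({exc})") from exc

    header = {c.strip().lower(): c for c in raw.columns}
    if column_map:
        for canonical, actual in column_map.items():
            actual_l = actual.strip().lower()
            if actual_l not in header:
                raise ValueError(f"{path}: mapped column {actual!r} not in header")
            header[canonical.lower()] = header.pop(actual_l)

    missing = [c for c in REQUIRED_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in header if c not in ALL_COLUMNS]
    if extra:
        logger.warning("%s: ignoring unrecognized columns %s", path, extra)
    for c in FLAG_FIELDS:
        if c not in header:
            logger.warning("%s: column %r absent; defaulting to False", path, c)

    records: list[SubjectRecord] = []
    excluded = 0
    for pos, (_, row) in enumerate(raw.iterrows()):
        problems: list[str] = []
        values: dict[str, object] = {}
        values["id"] = str(row[header["id"]]).strip() if pd.notna(row[header["id"]]) else f"row{pos}"
        sex = _parse_sex(row[header["sex"]])
        if sex is None:
            problems.append(f"sex: unparseable value {row[header['sex']]!r}")
        values["sex"] = sex or ""
        for name in NUMERIC_FIELDS:
            cell = row[header[name]]
            if pd.isna(cell) or str(cell).strip() == "":
                values[name] = float("nan")
                continue
            try:
                values[name] = float(cell)
            except ValueError:
                values[name] = float("nan")
                problems.append(f"{name}: non-numeric value {cell!r}")
        for name in FLAG_FIELDS:
            if name in header:
                flag = _parse_flag(row[header[name]])
                if flag is None and pd.notna(row[header[name]]) and str(row[header[name]]).strip() not in ("", "nan"):
                    problems.append(f"{name}: unparseable boolean {row[header[name]]!r}")
                values[name] = bool(flag) if flag is not None else False
            else:
                values[name] = False
        record = SubjectRecord(**values)  # type: ignore[arg-type]
        issues = validate_record(record)
        if problems and strict:
            raise ValueError(f"{path}: row {pos + 1}: " + "; ".join(problems))
        if issues or problems:
            if strict:
                raise ValueError(f"{path}: row {pos + 1}: " + "; ".join(str(i) for i in issues))
            excluded += 1
            logger.warning("%s: row %d excluded (%s)", path, pos + 1,
                           "; ".join(problems + [str(i) for i in issues]))
            continue
        records.append(record)
    return CohortTable(records=records, excluded_count=excluded)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort to CSV in the canonical dialect (sex M/F, flags 0/1)."""
    df = cohort.to_frame()
    df["sex"] = df["sex"].map({MALE: "M", FEMALE: "F"})
    for c in FLAG_FIELDS:
        df[c] = df[c].astype(int)
    df.to_csv(path, index=False)
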
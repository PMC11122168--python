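"""End-to-end analysis pipeline: indexes -> MetS classification -> stratified
ROC/Youden/likelihood-ratio evaluation -> group comparisons -> correlations.

`run_full_analysis` mirrors the structure of a diagnostic-accuracy study
report: a cohort characteristics block (mean +/- SD per group with p-value
bins), a prevalence block (overall, by sex, by age stratum), an ROC block
(three indexes x five strata), and a correlation block (each index against
the measured variables, the other indexes, and the 0/1-coded MetS status).
Everything in the report is a deterministic function of the input cohort and
the options, so regenerating it yields an identical JSON byte stream.
"""
from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import FEMALE, MALE, CohortTable
from .diagnostics import (fisher_exact, p_bin, pearson_with_strength,
                          roc_analyze, unpaired_t_test)
from .indices import panel_frame
from .mets import assessment_frame, percent

logger = logging.getLogger(__name__)

#: Age cut (years) separating the younger and older strata (inclusive below).
AGE_SPLIT = 50.0

INDEXES = ("bai", "lap", "cmi")

STRATA_ORDER = ("population", "males", "females", "younger", "older")

#: Continuous variables summarized in the characteristics block.
SUMMARY_VARS = ("age", "waist", "hip", "body_weight", "height", "bmi",
                "sbp", "dbp", "glucose", "total_chol", "hdl", "triglycerides",
                "bai", "lap", "cmi")

#: Columns correlated against each index in the correlation block.
CORRELATION_VARS = ("waist", "hip", "height", "body_weight", "bmi", "glucose",
                    "total_chol", "hdl", "triglycerides", "mets_01",
                    "bai", "lap", "cmi")


def stratify(cohort: CohortTable, scheme: str,
             assessments: pd.DataFrame | None = None) -> dict[str, CohortTable]:
    """Partition a cohort into named, disjoint subgroups.

    Schemes: ``all`` (identity), ``sex`` (males/females), ``age50``
    (younger: age <= 50; older: age > 50), ``mets_status`` (requires the
    per-subject assessment frame).  Empty strata are returned empty and
    flagged with a logged notice so callers can skip them.
    """
    df = cohort.to_frame()
    if scheme == "all":
        masks = {"population": np.ones(len(df), dtype=bool)}
    elif scheme == "sex":
        male = df["sex"].to_numpy() == MALE
        masks = {"males": male, "females": ~male}
    elif scheme == "age50":
        younger = df["age"].to_numpy(float) <= AGE_SPLIT
        masks = {"younger": younger, "older": ~younger}
    elif scheme == "mets_status":
        if assessments is None:
            raise ValueError("mets_status stratification requires assessments")
        pos = assessments["mets"].to_numpy(bool)
        masks = {"mets_pos": pos, "mets_neg": ~pos}
    else:
        raise ValueError(f"unknown stratification scheme {scheme!r}")
    out: dict[str, CohortTable] = {}
    for name, mask in masks.items():
        if not mask.any():
            logger.warning("stratum %r is empty; analyses of it will be skipped", name)
        out[name] = CohortTable(records=[cohort.records[i] for i in np.nonzero(mask)[0]])
    return out


def _strata_masks(df: pd.DataFrame) -> dict[str, np.ndarray]:
    male = df["sex"].to_numpy() == MALE
    younger = df["age"].to_numpy(float) <= AGE_SPLIT
    return {
        "population": np.ones(len(df), dtype=bool),
        "males": male,
        "females": ~male,
        "younger": younger,
        "older": ~younger,
    }


def _group_summary(values: np.ndarray) -> dict:
    return {"mean": float(np.mean(values)), "sd": float(np.std(values, ddof=1))
            if values.size > 1 else float("nan")}


def _comparison_block(df: pd.DataFrame, mask_a: np.ndarray, mask_b: np.ndarray,
                      label_a: str, label_b: str) -> dict:
    """Mean +/- SD per group and an unpaired t-test p-bin per variable,
    plus Fisher's exact test on the sex composition."""
    block: dict = {"groups": {label_a: {"n": int(mask_a.sum())},
                              label_b: {"n": int(mask_b.sum())}},
                   "variables": {}}
    for var in SUMMARY_VARS:
        a = df.loc[mask_a, var].to_numpy(float)
        b = df.loc[mask_b, var].to_numpy(float)
        entry = {label_a: _group_summary(a), label_b: _group_summary(b)}
        if a.size >= 2 and b.size >= 2:
            _, p = unpaired_t_test(a, b)
            entry["p_value"] = float(p)
            entry["p"] = p_bin(p)
        block["variables"][var] = entry
    sexes = df["sex"].to_numpy()
    table = [[int(((sexes == FEMALE) & mask_a).sum()), int(((sexes == FEMALE) & mask_b).sum())],
             [int(((sexes == MALE) & mask_a).sum()), int(((sexes == MALE) & mask_b).sum())]]
    if min(sum(table[0]), sum(table[1]), sum(r[0] for r in table), sum(r[1] for r in table)) > 0:
        p = fisher_exact(table)
        block["sex_composition"] = {"table_f_m_by_group": table,
                                    "p_value": float(p), "p": p_bin(p)}
    return block


def run_full_analysis(cohort: CohortTable, idf_strict: bool = False,
                      ci_method: str = "delong", level: float = 0.95,
                      n_boot: int = 2000, seed: int | None = None,
                      config_digest: str | None = None) -> dict:
    """Run the complete study workflow on one cohort.

    Returns a JSON-serializable report dict; see the module docstring for
    its blocks.  ``seed`` only matters when ``ci_method='bootstrap'``.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    df = cohort.to_frame()
    panels = panel_frame(df)
    assess = assessment_frame(df, idf_strict=idf_strict)
    work = pd.concat([df.reset_index(drop=True),
                      panels[["bmi", "bai", "lap", "cmi"]].reset_index(drop=True),
                      assess.reset_index(drop=True)], axis=1)
    work["mets_01"] = work["mets"].astype(int)
    masks = _strata_masks(work)
    labels_all = work["mets"].to_numpy(bool)

    # prevalence block
    prevalence: dict = {}
    for name in STRATA_ORDER:
        mask = masks[name]
        n = int(mask.sum())
        if n == 0:
            prevalence[name] = {"n": 0, "mets_count": 0, "prevalence_pct": None}
            continue
        k = int(labels_all[mask].sum())
        prevalence[name] = {"n": n, "mets_count": k, "prevalence_pct": percent(k, n)}
    from .mets import CRITERIA
    n_total = len(work)
    prevalence["criteria"] = {
        c: {"count": int(work[c].sum()), "pct": percent(int(work[c].sum()), n_total)}
        for c in CRITERIA}
    hist = work["criteria_count"].value_counts().sort_index()
    prevalence["criteria_count_histogram"] = {int(i): int(v) for i, v in hist.items()}

    # ROC block
    roc_block: dict = {}
    skipped: list[str] = []
    for name in STRATA_ORDER:
        mask = masks[name]
        y = labels_all[mask]
        roc_block[name] = {}
        if y.size == 0 or y.all() or not y.any() or y.sum() < 2 or (~y).sum() < 2:
            skipped.append(name)
            logger.warning("stratum %r skipped for ROC (single class or too small)", name)
            roc_block[name] = None
            continue
        for index_name in INDEXES:
            scores = work.loc[mask, index_name].to_numpy(float)
            res = roc_analyze(scores, y, level=level, ci_method=ci_method,
                              n_boot=n_boot, seed=seed)
            roc_block[name][index_name] = {
                "auc": res.auc, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "cutoff": res.cutoff,
                "sensitivity_pct": res.sensitivity_at_cutoff,
                "specificity_pct": res.specificity_at_cutoff,
                "youden_j": res.youden_j,
                "lr_pos": res.lr_pos, "lr_neg": res.lr_neg,
                "n_pos": res.n_pos, "n_neg": res.n_neg,
            }

    # group comparison blocks (MetS+/- and males/females)
    comparisons = {}
    mets_mask = labels_all
    if mets_mask.any() and (~mets_mask).any():
        comparisons["mets"] = _comparison_block(work, mets_mask, ~mets_mask,
                                                "mets_pos", "mets_neg")
    if masks["males"].any() and masks["females"].any():
        comparisons["sex"] = _comparison_block(work, masks["males"],
                                               masks["females"], "males", "females")

    # correlation block (Pearson; MetS enters 0/1-coded)
    correlations: dict = {}
    for name in ("population", "males", "females"):
        mask = masks[name]
        sub = work.loc[mask]
        correlations[name] = {}
        if len(sub) < 3:
            correlations[name] = None
            continue
        for index_name in INDEXES:
            correlations[name][index_name] = {}
            x = sub[index_name].to_numpy(float)
            for var in CORRELATION_VARS:
                if var == index_name:
                    continue
                y = sub[var].to_numpy(float)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    correlations[name][index_name][var] = None
                    continue
                res = pearson_with_strength(x, y)
                correlations[name][index_name][var] = {
                    "r": res.r, "r_squared": res.r_squared,
                    "p_value": res.p_value, "p": p_bin(res.p_value),
                    "strength": res.strength,
                }

    report = {
        "prevalence": prevalence,
        "roc": roc_block,
        "comparisons": comparisons,
        "correlations": correlations,
        "provenance": {
            "n_subjects": int(len(work)),
            "excluded_count": int(cohort.excluded_count),
            "idf_strict": bool(idf_strict),
            "ci_method": ci_method,
            "ci_level": level,
            "seed": seed,
            "config_digest": config_digest,
            "skipped_strata": skipped,
            "version": __version__,
        },
    }
    return report


def config_digest(config) -> str:
    """A short stable digest of a simulation config, for report provenance."""
    payload = {
        "n": config.n, "male_fraction": config.male_fraction,
        "marginals": {sex: {var: [m.mean, m.sd, m.family]
                            for var, m in config.marginals[sex].items()}
                      for sex in sorted(config.marginals)},
        "corr": np.asarray(config.corr).round(12).tolist(),
        "bounds": {k: list(v) for k, v in sorted(config.bounds.items())},
        "treatment_probs": list(config.treatment_probs),
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _sanitize(obj):
    """Make a report JSON-safe: numpy scalars -> python, non-finite -> None."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if math.isfinite(f) else None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def report_to_json(report: Mapping) -> str:
    """Canonical machine-readable form (sorted keys, 2-space indent)."""
    return json.dumps(_sanitize(report), sort_keys=True, indent=2)


def roc_table(report: Mapping) -> pd.DataFrame:
    """The ROC block as a flat table, one row per stratum x index."""
    rows = []
    for stratum in STRATA_ORDER:
        block = report["roc"].get(stratum)
        if not block:
            continue
        for index_name in INDEXES:
            entry = block[index_name]
            rows.append({"stratum": stratum, "index": index_name.upper(), **entry})
    return pd.DataFrame(rows)


def _fmt(x, digits=2):
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return "inf" if isinstance(x, float) and x == math.inf else "--"
    return f"{x:.{digits}f}"


def report_to_text(report: Mapping) -> str:
    """Aligned human-readable tables with binned p-values."""
    lines: list[str] = []
    prov = report["provenance"]
    lines.append(f"metsdx v{prov['version']} analysis report")
    lines.append(f"subjects: {prov['n_subjects']}  excluded: {prov['excluded_count']}"
                 f"  seed: {prov['seed']}  config: {prov['config_digest']}")
    lines.append("")
    lines.append("MetS prevalence")
    for name in STRATA_ORDER:
        entry = report["prevalence"][name]
        if entry["prevalence_pct"] is None:
            lines.append(f"  {name:<11} (empty)")
        else:
            lines.append(f"  {name:<11} {entry['mets_count']:>6}/{entry['n']:<6} "
                         f"{entry['prevalence_pct']:.1f}%")
    lines.append("")
    lines.append("ROC / Youden operating points (score >= cutoff is test-positive)")
    header = (f"  {'stratum':<11}{'index':<7}{'AUC':>6}{'95% CI':>16}{'cutoff':>9}"
              f"{'sens%':>8}{'spec%':>8}{'LR+':>7}{'LR-':>7}")
    lines.append(header)
    for stratum in STRATA_ORDER:
        block = report["roc"].get(stratum)
        if not block:
            lines.append(f"  {stratum:<11} (skipped)")
            continue
        for index_name in INDEXES:
            e = block[index_name]
            ci = f"({_fmt(e['ci_low'])}-{_fmt(e['ci_high'])})"
            lines.append(f"  {stratum:<11}{index_name.upper():<7}"
                         f"{_fmt(e['auc']):>6}{ci:>16}{_fmt(e['cutoff']):>9}"
                         f"{_fmt(e['sensitivity_pct']):>8}"
                         f"{_fmt(e['specificity_pct']):>8}"
                         f"{_fmt(e['lr_pos']):>7}{_fmt(e['lr_neg']):>7}")
    lines.append("")
    for key, title in (("mets", "MetS+ vs MetS-"), ("sex", "Males vs Females")):
        if key not in report["comparisons"]:
            continue
        block = report["comparisons"][key]
        (la, ga), (lb, gb) = list(block["groups"].items())
        lines.append(f"{title}  (n = {ga['n']} vs {gb['n']})")
        lines.append(f"  {'variable':<14}{la:>20}{lb:>20}{'p':>10}")
        for var, entry in block["variables"].items():
            sa = f"{_fmt(entry[la]['mean'], 1)} ± {_fmt(entry[la]['sd'], 1)}"
            sb = f"{_fmt(entry[lb]['mean'], 1)} ± {_fmt(entry[lb]['sd'], 1)}"
            lines.append(f"  {var:<14}{sa:>20}{sb:>20}{entry.get('p', '--'):>10}")
        if "sex_composition" in block:
            lines.append(f"  sex composition (Fisher): {block['sex_composition']['p']}")
        lines.append("")
    lines.append("Correlations (r, strength; MetS coded 0/1)")
    for name in ("population", "males", "females"):
        block = report["correlations"].get(name)
        if not block:
            continue
        lines.append(f"  [{name}]")
        for index_name in INDEXES:
            parts = []
            for var, entry in block[index_name].items():
                if entry is None:
                    continue
                parts.append(f"{var}: r={entry['r']:+.2f} ({entry['strength']}, {entry['p']})")
            lines.append(f"    {index_name.upper():<5} " + "; ".join(parts))
    lines.append("")
    return "\n".join(lines)


def render_report(report: Mapping, fmt: str, out_dir: str | Path) -> list[Path]:
    """Write a report to disk as ``json``, ``csv_bundle``, or ``text``.

    Returns the written paths.  ``csv_bundle`` emits one CSV per table
    analogue (roc, prevalence, comparisons, correlations).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt == "json":
        path = out / "report.json"
        path.write_text(report_to_json(report), encoding="utf-8")
        written.append(path)
    elif fmt == "text":
        path = out / "report.txt"
        path.write_text(report_to_text(report), encoding="utf-8")
        written.append(path)
    elif fmt == "csv_bundle":
        roc_df = roc_table(report)
        path = out / "roc.csv"
        roc_df.to_csv(path, index=False)
        written.append(path)
        prev_rows = []
        for name in STRATA_ORDER:
            e = report["prevalence"][name]
            prev_rows.append({"stratum": name, **e})
        path = out / "prevalence.csv"
        pd.DataFrame(prev_rows).to_csv(path, index=False)
        written.append(path)
        comp_rows = []
        for key, block in report["comparisons"].items():
            (la, _), (lb, _) = list(block["groups"].items())
            for var, entry in block["variables"].items():
                comp_rows.append({
                    "comparison": key, "variable": var,
                    f"mean_{la}": entry[la]["mean"], f"sd_{la}": entry[la]["sd"],
                    f"mean_{lb}": entry[lb]["mean"], f"sd_{lb}": entry[lb]["sd"],
                    "p": entry.get("p"),
                })
        path = out / "comparisons.csv"
        pd.DataFrame(comp_rows).to_csv(path, index=False)
        written.append(path)
        corr_rows = []
        for name, block in report["correlations"].items():
            if not block:
                continue
            for index_name, entries in block.items():
                for var, entry in entries.items():
                    if entry is None:
                        continue
                    corr_rows.append({"stratum": name, "index": index_name.upper(),
                                      "variable": var, **entry})
        path = out / "correlations.csv"
        pd.DataFrame(corr_rows).to_csv(path, index=False)
        written.append(path)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return written
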
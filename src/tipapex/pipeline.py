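"""End-to-end orchestration: measure, evaluate, flag.

``run_measure`` turns a landmark file into a per-case metrics table,
``run_evaluate`` joins metrics with outcomes and produces the report
tables (per-parameter ROC rows, categorical association tests,
proportion summaries), and ``run_flags`` applies the published
placement-safety rules per case.  All functions are deterministic for
fixed inputs; report rounding is centralised here (mm and percent to
one decimal, AUC to three decimals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as tio
from .metrics import compute_all_metrics
from .reference import SAFE_CLEVELAND_ZONES, THRESHOLD_RULES
from .stats import (
    ContingencyTable,
    DegenerateTableError,
    InsufficientDataError,
    RocResult,
    chi_square_test,
    proportion_summary,
    roc_analysis,
)

__all__ = [
    "DegenerateOutcomeError",
    "CONTINUOUS_PARAMETERS",
    "RISK_DIRECTIONS",
    "EvaluationReport",
    "run_measure",
    "run_evaluate",
    "run_flags",
    "round_report",
]

logger = logging.getLogger("tipapex")


class DegenerateOutcomeError(ValueError):
    """All outcomes identical: no discrimination analysis possible."""


#: Continuous parameters evaluated by default, with their risk direction:
#: +1 = high values flag risk, -1 = low values, "auto" = orient by AUC.
CONTINUOUS_PARAMETERS = [
    "tad_mm", "cal_tad_mm", "mtad_mm", "parker_ap_pct", "parker_lat_pct", "aba_deg",
]
RISK_DIRECTIONS = {
    "tad_mm": 1,
    "cal_tad_mm": 1,
    "mtad_mm": 1,
    "parker_ap_pct": 1,
    "parker_lat_pct": "auto",
    "aba_deg": -1,
}


def run_measure(landmarks_path, out_path=None, true_diameter_mm: float = 12.5):
    """Compute the metrics table for every case in a landmark file.

    Malformed rows are logged and skipped; returns
    ``(metrics_frame, skipped)``.
    """
    cases, skipped = tio.read_landmarks(landmarks_path, true_diameter_mm=true_diameter_mm)
    for row, reason in skipped:
        logger.warning("row %d skipped: %s", row, reason)
    metrics = [compute_all_metrics(case) for case in cases.values()]
    for m in metrics:
        for key, msg in m.errors.items():
            logger.warning("case %s: %s: %s", m.case_id, key, msg)
        if m.penetration_flag:
            logger.warning("case %s: screw tip penetrates the head surface", m.case_id)
    frame = tio.metrics_to_frame(metrics)
    if out_path is not None:
        tio.write_metrics(frame, out_path)
    return frame, skipped


@dataclass
class EvaluationReport:
    """Analysis-report bundle (one study's Results tables, recomputed)."""

    roc_table: pd.DataFrame
    associations: pd.DataFrame
    proportions: pd.DataFrame
    roc_results: dict[str, RocResult] = field(default_factory=dict)


def _categorical_association(
    name: str, groups: pd.Series, cutout: pd.Series
) -> Optional[dict]:
    table = pd.crosstab(groups, cutout)
    if table.shape[0] < 2 or table.shape[1] < 2:
        return None
    ct = ContingencyTable(
        row_labels=list(table.index),
        col_labels=list(table.columns),
        counts=table.to_numpy(),
    )
    try:
        res = chi_square_test(ct)
    except DegenerateTableError:
        return None
    return {
        "variable": name,
        "statistic": res.statistic,
        "df": res.df,
        "p_value": res.p_value,
        "method": res.method_used,
    }


def run_evaluate(
    metrics: pd.DataFrame,
    outcomes: pd.DataFrame,
    parameters: Optional[list[str]] = None,
) -> EvaluationReport:
    """Join metrics with outcomes and run the full comparison.

    One ROC row per requested continuous parameter (missing values are
    dropped per parameter), chi-square/exact association rows for the
    categorical covariates and Cleveland-zone-1 membership, and
    proportion summaries of the cut-out outcome.
    """
    parameters = list(parameters) if parameters is not None else list(CONTINUOUS_PARAMETERS)
    merged = metrics.merge(outcomes, on="case_id", how="inner", validate="one_to_one")
    if merged.empty:
        raise ValueError("metrics and outcomes share no case_id")
    cutout = merged["cutout"].astype(int)
    if cutout.nunique() < 2:
        raise DegenerateOutcomeError(
            f"outcome has no variation (all {'cut-out' if cutout.iloc[0] else 'intact'})"
        )

    roc_rows = []
    roc_results: dict[str, RocResult] = {}
    for name in parameters:
        if name not in merged.columns:
            logger.warning("parameter %s absent from metrics; skipped", name)
            continue
        values = pd.to_numeric(merged[name], errors="coerce")
        ok = values.notna()
        try:
            res = roc_analysis(
                values[ok].to_numpy(),
                cutout[ok].to_numpy(),
                parameter_name=name,
                direction=RISK_DIRECTIONS.get(name, "auto"),
            )
        except InsufficientDataError as exc:
            logger.warning("parameter %s: %s", name, exc)
            continue
        roc_results[name] = res
        roc_rows.append(
            {
                "parameter": name,
                "auc": res.auc,
                "p_value": res.p_value,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "cutoff": res.cutoff,
                "cutoff_clinical": res.cutoff_clinical,
                "sensitivity_pct": res.sensitivity_pct,
                "specificity_pct": res.specificity_pct,
                "direction": res.direction,
                "n_used": int(ok.sum()),
            }
        )

    assoc_rows = []
    for var in ("pattern", "reduction"):
        if var in merged.columns:
            row = _categorical_association(var, merged[var], cutout)
            if row:
                assoc_rows.append(row)
    if "cleveland_zone" in merged.columns:
        zone1 = pd.to_numeric(merged["cleveland_zone"], errors="coerce") == 1
        row = _categorical_association("cleveland_zone_1", zone1.map({True: "zone 1", False: "other"}), cutout)
        if row:
            assoc_rows.append(row)

    prop_rows = [
        {
            "group": "overall",
            "n_cutout": int(cutout.sum()),
            "n_total": int(len(cutout)),
            "cutout_pct": proportion_summary(int(cutout.sum()), int(len(cutout))),
        }
    ]
    if "pattern" in merged.columns:
        for pattern, sub in merged.groupby("pattern"):
            prop_rows.append(
                {
                    "group": f"pattern {pattern}",
                    "n_cutout": int(sub["cutout"].sum()),
                    "n_total": int(len(sub)),
                    "cutout_pct": proportion_summary(int(sub["cutout"].sum()), int(len(sub))),
                }
            )

    return EvaluationReport(
        roc_table=pd.DataFrame(roc_rows),
        associations=pd.DataFrame(assoc_rows),
        proportions=pd.DataFrame(prop_rows),
        roc_results=roc_results,
    )


_OPS = {
    "<": lambda v, t: v < t,
    "<=": lambda v, t: v <= t,
    ">": lambda v, t: v > t,
    ">=": lambda v, t: v >= t,
    "in": lambda v, t: v in t,
}


def run_flags(metrics: pd.DataFrame, rules: Optional[dict] = None) -> pd.DataFrame:
    """Per-case placement-safety flags.

    One boolean column per rule (pandas nullable booleans: <NA> when the
    underlying metric is missing) plus ``n_rules_passed`` counting the
    rules that evaluate True.
    """
    rules = dict(THRESHOLD_RULES) if rules is None else dict(rules)
    out = pd.DataFrame({"case_id": metrics["case_id"]})
    flag_cols = []
    for column, (op, threshold) in rules.items():
        if op == "in":
            name = f"{column}_safe"
        else:
            name = f"{column}_{ {'<': 'lt', '<=': 'le', '>': 'gt', '>=': 'ge'}[op] }_{threshold:g}"
        flag_cols.append(name)
        if column not in metrics.columns:
            out[name] = pd.array([pd.NA] * len(metrics), dtype="boolean")
            continue
        values = pd.to_numeric(metrics[column], errors="coerce")
        flags = values.map(lambda v: pd.NA if pd.isna(v) else _OPS[op](v, threshold))
        out[name] = pd.array(flags, dtype="boolean")
    out["n_rules_passed"] = sum(out[c].fillna(False).astype(int) for c in flag_cols)
    return out


def round_report(report: EvaluationReport) -> EvaluationReport:
    """Report-format rounding: mm/% one decimal, AUC three, p four."""
    roc = report.roc_table.copy()
    if not roc.empty:
        for col in ("cutoff", "cutoff_clinical", "sensitivity_pct", "specificity_pct"):
            roc[col] = roc[col].round(1)
        for col in ("auc", "ci_low", "ci_high"):
            roc[col] = roc[col].round(3)
        roc["p_value"] = roc["p_value"].round(4)
    assoc = report.associations.copy()
    if not assoc.empty:
        assoc["statistic"] = assoc["statistic"].round(2)
        assoc["p_value"] = assoc["p_value"].round(4)
    return EvaluationReport(roc, assoc, report.proportions.copy(), report.roc_results)
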
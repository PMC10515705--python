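"""Reading and writing the landmark / outcome / metrics table formats.

Landmark files carry one row per case per view.  Coordinates are in
image units in an arbitrary image frame whose +y axis is superior (AP)
or anterior (LAT).  The ``side`` column (L/R) states which hip was
imaged; rows for right hips are mirrored on read (x and x-components
negated) so that downstream geometry always sees the canonical
*medial = +x* orientation.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .geometry import DEFAULT_SCREW_DIAMETER_MM, LandmarkError, View, ViewLandmarks
from .metrics import CaseRadiographs, ScrewMetrics

__all__ = [
    "LANDMARK_COLUMNS",
    "METRIC_COLUMNS",
    "read_landmarks",
    "write_landmarks",
    "read_outcomes",
    "write_outcomes",
    "metrics_to_frame",
    "write_metrics",
    "read_metrics",
]

LANDMARK_COLUMNS = [
    "case_id", "view", "side",
    "head_cx", "head_cy", "head_r",
    "neck_px", "neck_py", "neck_dx", "neck_dy",
    "tip_x", "tip_y", "screw_dx", "screw_dy",
    "screw_diam_units", "calcar_x", "calcar_y",
]

METRIC_COLUMNS = [
    "case_id", "tad_mm", "cal_tad_mm", "mtad_mm",
    "parker_ap_pct", "parker_lat_pct", "cleveland_zone", "aba_deg",
    "ab_ap_mm", "bc_ap_mm", "bc_sign", "penetration_flag", "errors",
]

_X_FIELDS = ["head_cx", "neck_px", "neck_dx", "tip_x", "screw_dx", "calcar_x"]


def _row_to_view(row: dict) -> ViewLandmarks:
    mirror = -1.0 if str(row["side"]).strip().upper() == "R" else 1.0

    def num(key: str) -> float:
        value = float(row[key])
        if not math.isfinite(value):
            raise ValueError(f"non-finite {key}")
        return value

    def pt(xk: str, yk: str) -> tuple[float, float]:
        return (mirror * num(xk), num(yk))

    calcar = None
    cx, cy = row.get("calcar_x"), row.get("calcar_y")
    if cx is not None and cy is not None and not (_blank(cx) or _blank(cy)):
        calcar = (mirror * float(cx), float(cy))
    return ViewLandmarks(
        view_label=View(str(row["view"]).strip().upper()),
        head_center=pt("head_cx", "head_cy"),
        head_radius=num("head_r"),
        neck_axis_point=pt("neck_px", "neck_py"),
        neck_axis_dir=pt("neck_dx", "neck_dy"),
        screw_tip=pt("tip_x", "tip_y"),
        screw_axis_dir=pt("screw_dx", "screw_dy"),
        screw_diameter_measured=num("screw_diam_units"),
        calcar_point=calcar,
    )


def _blank(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return str(value).strip() == ""


def read_landmarks(
    path, true_diameter_mm: float = DEFAULT_SCREW_DIAMETER_MM
) -> tuple[dict[str, CaseRadiographs], list[tuple[int, str]]]:
    """Read a landmark CSV/JSON file into per-case radiograph pairs.

    Returns ``(cases, skipped)`` where ``skipped`` lists
    ``(row_number, reason)`` for malformed rows and for cases missing
    one of the two views.  Row numbers are 1-based data rows.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        frame = pd.DataFrame(rows)
    else:
        frame = pd.read_csv(path, dtype={"case_id": str})
    missing_cols = [c for c in LANDMARK_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing landmark columns {missing_cols}")

    views: dict[str, dict[View, ViewLandmarks]] = {}
    first_row: dict[str, int] = {}
    skipped: list[tuple[int, str]] = []
    for i, row in enumerate(frame.to_dict("records"), start=1):
        case_id = str(row.get("case_id", "")).strip()
        try:
            if not case_id or _blank(row.get("case_id")):
                raise ValueError("missing case_id")
            lm = _row_to_view(row)
        except (ValueError, KeyError, LandmarkError) as exc:
            skipped.append((i, f"malformed row: {exc}"))
            continue
        slot = views.setdefault(case_id, {})
        if lm.view_label in slot:
            skipped.append((i, f"duplicate {lm.view_label.value} view for case {case_id}"))
            continue
        slot[lm.view_label] = lm
        first_row.setdefault(case_id, i)

    cases: dict[str, CaseRadiographs] = {}
    for case_id, slot in views.items():
        if View.AP in slot and View.LAT in slot:
            cases[case_id] = CaseRadiographs(
                case_id=case_id,
                ap=slot[View.AP],
                lat=slot[View.LAT],
                true_diameter_mm=true_diameter_mm,
            )
        else:
            have = ", ".join(v.value for v in slot)
            skipped.append((first_row[case_id], f"case {case_id}: incomplete views ({have})"))
    return cases, skipped


def write_landmarks(frame: pd.DataFrame, path) -> None:
    """Write a landmark table (already in file orientation) to CSV."""
    frame.to_csv(path, index=False, columns=LANDMARK_COLUMNS)


def read_outcomes(path) -> pd.DataFrame:
    """Outcomes CSV: case_id, pattern, reduction, singh, cutout (0/1 or Y/N)."""
    frame = pd.read_csv(path, dtype={"case_id": str})
    required = {"case_id", "cutout"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing outcome columns {sorted(missing)}")
    frame["cutout"] = (
        frame["cutout"].map(lambda v: {"Y": 1, "N": 0}.get(str(v).strip().upper(), v)).astype(int)
    )
    if not frame["cutout"].isin([0, 1]).all():
        raise ValueError(f"{path}: cutout must be binary (0/1 or Y/N)")
    return frame


def write_outcomes(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def metrics_to_frame(metrics: Iterable[ScrewMetrics]) -> pd.DataFrame:
    rows = []
    for m in metrics:
        row = {c: getattr(m, c) for c in METRIC_COLUMNS if c != "errors"}
        row["errors"] = "; ".join(f"{k}: {v}" for k, v in m.errors.items())
        rows.append(row)
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def write_metrics(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"case_id": str})
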
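"""The six lag-screw position parameters for one fixed hip.

Given calibrated AP and lateral landmark sets this module computes:

* **TAD** — Baumgaertner's tip-apex distance: the AP tip-to-apex
  distance plus the lateral tip-to-apex distance, each calibrated in
  its own view.
* **Cal TAD** — calcar-referenced TAD: the AP reference axis is
  translated inferiorly to run through the calcar cortex; the AP term
  is measured from the screw tip to that axis's medial head-surface
  intersection.  The lateral term is unchanged.
* **Modified TAD (mTAD)** — the lateral TAD term plus an AP *net*
  distance AB ± BC, where A is the screw tip, B the far head-surface
  point along the screw axis, and C the head apex.  AB is always
  positive (negative only for a tip that has penetrated the surface);
  BC takes the sign of B's position relative to the neck central axis:
  positive superior, negative inferior.  A central screw has B = C and
  mTAD = TAD; an inferior screw scores lower than a superior screw of
  equal insertion depth, encoding the direction of the screw as well
  as its depth.
* **Parker's ratio** (AP and LAT) — position of the screw axis across
  the head, as a percentage of the head diameter perpendicular to the
  neck axis, measured from the inferior (AP) / anterior (LAT) end.
* **Cleveland zone** — 3x3 grid cell (superior/central/inferior x
  anterior/central/posterior) containing the screw tip; zone 1 is
  superior-anterior, zone 9 inferior-posterior.
* **ABA** — axis-blade angle: signed AP angle between neck axis and
  screw axis, negative for superior deviation of the screw tip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import (
    DEFAULT_SCREW_DIAMETER_MM,
    Calibration,
    LandmarkError,
    MissingLandmarkError,
    NoIntersectionError,
    View,
    ViewLandmarks,
    apex_point,
    calibration_for_view,
    line_circle_far_intersection,
    line_circle_intersections,
    signed_offset_from_axis,
)

__all__ = [
    "CaseRadiographs",
    "ScrewMetrics",
    "MTadComponents",
    "OutOfHeadError",
    "UndefinedRatioError",
    "tad",
    "cal_tad",
    "modified_tad",
    "parker_ratio",
    "cleveland_zone",
    "axis_blade_angle",
    "compute_all_metrics",
]

# Offsets smaller than this (mm) count as "on the neck axis": bc_sign = 0.
_CENTRAL_TOL_MM = 1e-6

_POSITIVE_SIDE = np.array([0.0, 1.0])  # superior (AP) / anterior (LAT)


class OutOfHeadError(LandmarkError):
    """Screw tip lies outside the femoral head circle.

    Carries the zone of the nearest in-head position as a diagnostic.
    """

    def __init__(self, message: str, nearest_zone: int):
        super().__init__(message)
        self.nearest_zone = nearest_zone


class UndefinedRatioError(LandmarkError):
    """Screw axis is parallel to the Parker measurement chord."""


@dataclass
class CaseRadiographs:
    """Paired AP + lateral landmark sets for one case."""

    case_id: str
    ap: ViewLandmarks
    lat: ViewLandmarks
    true_diameter_mm: float = DEFAULT_SCREW_DIAMETER_MM

    def __post_init__(self) -> None:
        if self.ap.view_label is not View.AP:
            raise LandmarkError(f"case {self.case_id}: 'ap' landmarks labelled {self.ap.view_label}")
        if self.lat.view_label is not View.LAT:
            raise LandmarkError(f"case {self.case_id}: 'lat' landmarks labelled {self.lat.view_label}")

    def calibration(self, view: View) -> Calibration:
        lm = self.ap if view is View.AP else self.lat
        return calibration_for_view(lm, self.true_diameter_mm)


@dataclass
class MTadComponents:
    """Audit decomposition of the modified TAD."""

    mtad_mm: float
    ab_ap_mm: float      # tip -> far-surface point B along screw axis (signed; < 0 = penetration)
    bc_ap_mm: float      # unsigned chord B -> apex
    bc_sign: int         # +1 superior, -1 inferior, 0 on the neck axis
    lat_term_mm: float   # lateral tip-apex distance
    penetration: bool


@dataclass
class ScrewMetrics:
    """All six position parameters for one case.

    Metrics whose geometry is invalid for this case are ``None`` with
    the reason recorded in ``errors`` under the metric name.
    """

    case_id: str
    tad_mm: Optional[float] = None
    cal_tad_mm: Optional[float] = None
    mtad_mm: Optional[float] = None
    parker_ap_pct: Optional[float] = None
    parker_lat_pct: Optional[float] = None
    cleveland_zone: Optional[int] = None
    aba_deg: Optional[float] = None
    ab_ap_mm: Optional[float] = None
    bc_ap_mm: Optional[float] = None
    bc_sign: Optional[int] = None
    penetration_flag: bool = False
    errors: dict = field(default_factory=dict)


def _tip_apex_mm(lm: ViewLandmarks, true_diameter_mm: float) -> float:
    """Calibrated straight-line tip-to-apex distance in one view."""
    cal = calibration_for_view(lm, true_diameter_mm)
    apex = apex_point(lm)
    return cal.to_mm(float(np.linalg.norm(lm.screw_tip - apex)))


def tad(case: CaseRadiographs) -> float:
    """Tip-apex distance: AP term + LAT term, each calibrated per view."""
    return _tip_apex_mm(case.ap, case.true_diameter_mm) + _tip_apex_mm(
        case.lat, case.true_diameter_mm
    )


def cal_tad(case: CaseRadiographs) -> float:
    """Calcar-referenced TAD.

    The AP reference axis is the line through the calcar point parallel
    to the neck axis; the AP term runs from the screw tip to that
    axis's medial head-surface intersection.  LAT term as in TAD.
    """
    lm = case.ap
    if lm.calcar_point is None:
        raise MissingLandmarkError(f"case {case.case_id}: calcar_point required for Cal TAD")
    try:
        ref = line_circle_far_intersection(
            lm.calcar_point, lm.neck_axis_dir, lm.head_center, lm.head_radius
        )
    except NoIntersectionError as exc:
        raise LandmarkError(
            f"case {case.case_id}: calcar-referenced axis misses the head circle"
        ) from exc
    cal = calibration_for_view(lm, case.true_diameter_mm)
    ap_term = cal.to_mm(float(np.linalg.norm(lm.screw_tip - ref)))
    return ap_term + _tip_apex_mm(case.lat, case.true_diameter_mm)


def modified_tad(case: CaseRadiographs) -> MTadComponents:
    """Modified TAD with its audit components.

    AP part = AB + sign * BC, calibrated with the AP scale; the lateral
    part is the ordinary lateral tip-apex distance.  AB is the signed
    distance from the tip to the far head-surface point B along the
    screw axis (negative exactly when the tip has penetrated beyond the
    surface, which is flagged rather than fatal); BC is the straight
    chord from B to the apex C, signed by B's side of the neck axis.
    """
    lm = case.ap
    _, t_far = line_circle_intersections(
        lm.screw_tip, lm.screw_axis_dir, lm.head_center, lm.head_radius
    )
    b_point = lm.screw_tip + t_far * lm.screw_axis_dir
    c_point = apex_point(lm)
    ab_units = t_far  # signed distance along the unit screw axis
    bc_units = float(np.linalg.norm(c_point - b_point))

    cal = calibration_for_view(lm, case.true_diameter_mm)
    ab_mm = cal.to_mm(ab_units)
    bc_mm = cal.to_mm(bc_units)
    offset_mm = cal.to_mm(
        signed_offset_from_axis(b_point, lm.neck_axis_point, lm.neck_axis_dir, _POSITIVE_SIDE)
    )
    if abs(offset_mm) < _CENTRAL_TOL_MM:
        sign = 0
    else:
        sign = 1 if offset_mm > 0 else -1

    lat_term = _tip_apex_mm(case.lat, case.true_diameter_mm)
    return MTadComponents(
        mtad_mm=ab_mm + sign * bc_mm + lat_term,
        ab_ap_mm=ab_mm,
        bc_ap_mm=bc_mm,
        bc_sign=sign,
        lat_term_mm=lat_term,
        penetration=ab_mm < 0,
    )


def parker_ratio(case: CaseRadiographs, view: View) -> float:
    """Parker's ratio in one view, percent.

    Measured across the head-circle diameter perpendicular to the neck
    axis: 100 x (distance from the inferior (AP) / anterior (LAT) end
    of that diameter to the screw-axis crossing) / (diameter).  Values
    outside [0, 100] mean the screw axis crosses beyond the head and
    are returned as-is for the caller to flag.
    """
    view = View(view)
    lm = case.ap if view is View.AP else case.lat
    d = lm.neck_axis_dir
    normal = np.array([-d[1], d[0]])
    if normal[1] < 0:  # orient toward +y (superior / anterior)
        normal = -normal
    # Chord runs from end0 to end1; end0 is the 0% anchor.
    if view is View.AP:
        end0 = lm.head_center - lm.head_radius * normal  # inferior end
        chord_dir = normal
    else:
        end0 = lm.head_center + lm.head_radius * normal  # anterior end
        chord_dir = -normal
    s = lm.screw_axis_dir
    denom = float(s[0] * chord_dir[1] - s[1] * chord_dir[0])
    if abs(denom) < 1e-12:
        raise UndefinedRatioError(
            f"case {case.case_id} {view.value}: screw axis parallel to the Parker chord"
        )
    # Solve end0 + u*chord_dir = tip + v*screw_dir for u.
    delta = lm.screw_tip - end0
    u = float(delta[0] * s[1] - delta[1] * s[0]) / -denom
    return 100.0 * u / (2.0 * lm.head_radius)


def _zone_band(offset: float, radius: float) -> int:
    """1 = positive-side third, 2 = central, 3 = negative-side third."""
    if offset > radius / 3.0:
        return 1
    if offset < -radius / 3.0:
        return 3
    return 2


def cleveland_zone(case: CaseRadiographs) -> int:
    """Cleveland zone (1-9) of the screw tip.

    Row from the AP superior offset (superior/central/inferior thirds of
    the head), column from the LAT anterior offset; zone = 3*(row-1)+col,
    so zone 1 is superior-anterior and the safe set {5, 6, 8, 9} is the
    central-to-inferior, central-to-posterior block.
    """
    bands = []
    out_of_head = []
    for lm in (case.ap, case.lat):
        off = signed_offset_from_axis(
            lm.screw_tip, lm.neck_axis_point, lm.neck_axis_dir, _POSITIVE_SIDE
        )
        bands.append(_zone_band(off, lm.head_radius))
        out_of_head.append(
            float(np.linalg.norm(lm.screw_tip - lm.head_center)) > lm.head_radius * (1 + 1e-9)
        )
    row, col = bands
    zone = 3 * (row - 1) + col
    if any(out_of_head):
        views = [v for v, bad in zip(("AP", "LAT"), out_of_head) if bad]
        raise OutOfHeadError(
            f"case {case.case_id}: screw tip outside the head circle in {'/'.join(views)}; "
            f"nearest zone {zone}",
            nearest_zone=zone,
        )
    return zone


def axis_blade_angle(case: CaseRadiographs) -> float:
    """Axis-blade angle, signed degrees, AP view.

    Angle between the neck axis and the screw axis; negative when the
    screw deviates superiorly from the neck axis, positive inferiorly,
    so the usual safety rule reads ABA > -10 deg ("no more than 10
    degrees of superior deviation").
    """
    n = case.ap.neck_axis_dir
    s = case.ap.screw_axis_dir
    cross = float(n[0] * s[1] - n[1] * s[0])
    dot = float(np.dot(n, s))
    return -math.degrees(math.atan2(cross, dot))


def compute_all_metrics(case: CaseRadiographs) -> ScrewMetrics:
    """All six parameters; per-metric failures are recorded, not raised."""
    m = ScrewMetrics(case_id=case.case_id)

    try:
        m.tad_mm = tad(case)
    except LandmarkError as exc:
        m.errors["tad_mm"] = str(exc)
    try:
        m.cal_tad_mm = cal_tad(case)
    except LandmarkError as exc:
        m.errors["cal_tad_mm"] = str(exc)
    try:
        comp = modified_tad(case)
        m.mtad_mm = comp.mtad_mm
        m.ab_ap_mm = comp.ab_ap_mm
        m.bc_ap_mm = comp.bc_ap_mm
        m.bc_sign = comp.bc_sign
        m.penetration_flag = comp.penetration
    except LandmarkError as exc:
        m.errors["mtad_mm"] = str(exc)
    for name, view in (("parker_ap_pct", View.AP), ("parker_lat_pct", View.LAT)):
        try:
            value = parker_ratio(case, view)
            setattr(m, name, value)
            if not 0.0 <= value <= 100.0:
                m.errors[name + "_range"] = f"value {value:.1f} outside [0, 100]"
        except LandmarkError as exc:
            m.errors[name] = str(exc)
    try:
        m.cleveland_zone = cleveland_zone(case)
    except OutOfHeadError as exc:
        m.errors["cleveland_zone"] = str(exc)
    except LandmarkError as exc:
        m.errors["cleveland_zone"] = str(exc)
    try:
        m.aba_deg = axis_blade_angle(case)
    except LandmarkError as exc:
        m.errors["aba_deg"] = str(exc)
    return m
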
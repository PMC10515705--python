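"""Calibrated 2-D geometry of a single hip radiograph view.

A radiographic view is modelled in continuous 2-D coordinates with the
femoral head as a circle.  The canonical orientation is *medial = +x*;
the second axis is *superior = +y* in the AP view and *anterior = +y* in
the lateral view (hip side is normalised to this frame at file-read
time, see :mod:`tipapex.io`).

Distances measured on a radiograph are in arbitrary image units and are
converted to millimetres through the known lag-screw diameter (12.5 mm
for a standard DHS lag screw), which appears magnified by the same
factor as every other structure in the view.  Each view carries its own
magnification, so calibration is strictly per view.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "View",
    "ViewLandmarks",
    "Calibration",
    "LandmarkError",
    "NoIntersectionError",
    "MissingLandmarkError",
    "DEFAULT_SCREW_DIAMETER_MM",
    "calibration_for_view",
    "line_circle_intersections",
    "line_circle_far_intersection",
    "apex_point",
    "signed_offset_from_axis",
]

#: Nominal DHS lag-screw diameter used as the in-image calibration object.
DEFAULT_SCREW_DIAMETER_MM = 12.5


class LandmarkError(ValueError):
    """An annotated landmark set is geometrically or numerically invalid."""


class NoIntersectionError(LandmarkError):
    """A required line--circle intersection does not exist."""


class MissingLandmarkError(LandmarkError):
    """A landmark required by the requested metric was not annotated."""


class View(str, enum.Enum):
    AP = "AP"
    LAT = "LAT"


def _as_point(p: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.shape != (2,) or not np.all(np.isfinite(arr)):
        raise LandmarkError(f"{name} must be a finite 2-D point, got {p!r}")
    return arr


def _as_unit(v: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (2,) or not np.all(np.isfinite(arr)):
        raise LandmarkError(f"{name} must be a finite 2-vector, got {v!r}")
    norm = float(np.linalg.norm(arr))
    if norm < 1e-12:
        raise LandmarkError(f"{name} is degenerate (zero length)")
    return arr / norm


@dataclass
class ViewLandmarks:
    """Annotated landmarks of one radiographic view, in image units.

    Direction vectors are normalised on construction and must point
    medially (toward the femoral head apex, +x in the canonical frame).
    ``calcar_point`` is any point on the medial calcar cortex and is
    only meaningful — and only required — in the AP view, where it
    anchors the calcar-referenced TAD axis.
    """

    view_label: View
    head_center: np.ndarray
    head_radius: float
    neck_axis_point: np.ndarray
    neck_axis_dir: np.ndarray
    screw_tip: np.ndarray
    screw_axis_dir: np.ndarray
    screw_diameter_measured: float
    calcar_point: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.view_label = View(self.view_label)
        self.head_center = _as_point(self.head_center, "head_center")
        self.neck_axis_point = _as_point(self.neck_axis_point, "neck_axis_point")
        self.screw_tip = _as_point(self.screw_tip, "screw_tip")
        self.neck_axis_dir = _as_unit(self.neck_axis_dir, "neck_axis_dir")
        self.screw_axis_dir = _as_unit(self.screw_axis_dir, "screw_axis_dir")
        self.head_radius = float(self.head_radius)
        self.screw_diameter_measured = float(self.screw_diameter_measured)
        if not self.head_radius > 0:
            raise LandmarkError(f"head_radius must be > 0, got {self.head_radius}")
        if not self.screw_diameter_measured > 0:
            raise LandmarkError(
                f"screw_diameter_measured must be > 0, got {self.screw_diameter_measured}"
            )
        if self.calcar_point is not None:
            self.calcar_point = _as_point(self.calcar_point, "calcar_point")


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-millimetre scale of one view.

    ``scale`` multiplies any in-view distance (image units) to yield
    millimetres: scale = true screw diameter / measured screw diameter.
    """

    scale: float
    true_diameter_mm: float = DEFAULT_SCREW_DIAMETER_MM

    def to_mm(self, distance_image_units: float) -> float:
        return self.scale * distance_image_units


def calibration_for_view(
    lm: ViewLandmarks, true_diameter_mm: float = DEFAULT_SCREW_DIAMETER_MM
) -> Calibration:
    """Per-view calibration from the measured lag-screw diameter."""
    if not lm.screw_diameter_measured > 0:
        raise LandmarkError("measured screw diameter must be positive")
    if not true_diameter_mm > 0:
        raise LandmarkError("true screw diameter must be positive")
    return Calibration(
        scale=true_diameter_mm / lm.screw_diameter_measured,
        true_diameter_mm=true_diameter_mm,
    )


def line_circle_intersections(
    origin: Sequence[float],
    direction: Sequence[float],
    center: Sequence[float],
    radius: float,
) -> tuple[float, float]:
    """Parameters ``(t_near, t_far)`` of the two line--circle intersections.

    The line is ``origin + t * direction`` with unit ``direction``; the
    intersection points sit at the returned parameters, ``t_near <= t_far``.
    A tangent line yields ``t_near == t_far``.

    Raises
    ------
    NoIntersectionError
        If the line misses the circle (negative discriminant).
    """
    o = _as_point(origin, "origin")
    d = _as_unit(direction, "direction")
    c = _as_point(center, "center")
    if not radius > 0:
        raise LandmarkError(f"radius must be > 0, got {radius}")
    oc = o - c
    # |oc + t d|^2 = r^2 with |d| = 1  ->  t^2 + 2 b t + c0 = 0
    b = float(np.dot(oc, d))
    c0 = float(np.dot(oc, oc)) - radius * radius
    disc = b * b - c0
    if disc < 0:
        raise NoIntersectionError(
            f"line through {tuple(o)} dir {tuple(d)} misses circle "
            f"(center {tuple(c)}, r {radius}); discriminant {disc:.6g}"
        )
    root = math.sqrt(disc)
    return (-b - root, -b + root)


def line_circle_far_intersection(
    origin: Sequence[float],
    direction: Sequence[float],
    center: Sequence[float],
    radius: float,
) -> np.ndarray:
    """Far (larger-parameter, medial-side) intersection of a line and circle.

    With ``direction`` pointing medially this is the head-surface point on
    the far side of the screw trajectory — point B of the modified-TAD
    construction when the line is the screw axis.  The parameter of the
    returned point may be negative (origin beyond the far surface, i.e. a
    penetrating tip); callers decide how to flag that.
    """
    o = _as_point(origin, "origin")
    d = _as_unit(direction, "direction")
    _, t_far = line_circle_intersections(o, d, center, radius)
    return o + t_far * d


def apex_point(lm: ViewLandmarks) -> np.ndarray:
    """Femoral head apex: medial intersection of the neck axis with the head.

    The head is modelled as a circle; the apex (point C of the tip-apex
    construction) is where the femoral neck central axis pierces the head
    surface on the medial side — the far intersection along the medially
    pointing neck axis.  For a screw lying exactly on the neck axis the
    apex coincides with the screw-axis far-surface point.
    """
    try:
        return line_circle_far_intersection(
            lm.neck_axis_point, lm.neck_axis_dir, lm.head_center, lm.head_radius
        )
    except NoIntersectionError as exc:
        raise LandmarkError(f"neck axis misses the head circle: {exc}") from exc


def signed_offset_from_axis(
    p: Sequence[float],
    axis_point: Sequence[float],
    axis_dir: Sequence[float],
    positive_side: Sequence[float],
) -> float:
    """Signed perpendicular distance of ``p`` from an axis line.

    Positive when ``p`` lies on the half-plane indicated by
    ``positive_side`` (superior in AP, anterior in LAT under the canonical
    frame), negative on the opposite side, zero on the axis.
    ``positive_side`` need not be exactly perpendicular to the axis; it
    only orients the axis normal and must not be parallel to the axis.
    """
    pt = _as_point(p, "p")
    a0 = _as_point(axis_point, "axis_point")
    d = _as_unit(axis_dir, "axis_dir")
    side = _as_unit(positive_side, "positive_side")
    normal = np.array([-d[1], d[0]])
    orient = float(np.dot(normal, side))
    if abs(orient) < 1e-12:
        raise LandmarkError("positive_side is parallel to the axis; cannot orient")
    if orient < 0:
        normal = -normal
    return float(np.dot(pt - a0, normal))
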
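"""Anatomical landmark localization on lung contours.

Landmarks (patient-side naming; patient-right = image-left):

* ``A1``/``A2`` — lung apices (topmost boundary points).
* ``B1``/``B2`` — costophrenic angles (inferior-lateral corners).
* ``C1``/``C2`` — cardiophrenic angles: on the medial apex-to-costophrenic
  arc, the point farthest from the apex-costophrenic chord.
* ``C1p``/``C2p`` — termination points bounding the cardiac-margin search
  superiorly.
* ``D1`` — top of the right hemi-diaphragm.
* ``D2p``/``D3p`` — thoracic inner-edge extremes (min-x of the right lung,
  max-x of the left); their x-span is the thoracic transverse diameter.
* ``E1``/``E2`` — heart-border points: on the medial edge between the
  cardiophrenic angle and the termination point, the point of maximum
  perpendicular distance to the vertical midline O-O'.  Since all
  candidates lie strictly on one side of the midline, this argmax equals
  the medially-indented extreme-x point and is independent of the exact
  midline position (the midline matters for reporting only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

from .contours import Contour, MedialProfile, PATIENT_LEFT, PATIENT_RIGHT, contour_arc, _both_arcs
from .errors import LandmarkError
from .mask_io import Point


@dataclass(frozen=True)
class MidLine:
    """Vertical reference line O-O': a0*x + c0 = 0, i.e. x0 = -c0/a0.

    Approximates the spine on the radiograph.  The general oblique form
    a0*x + b0*y + c0 = 0 specializes to b0 = 0 here.
    """

    a0: float
    c0: float
    b0: float = 0.0

    def __post_init__(self):
        if self.a0 == 0:
            raise LandmarkError("midline requires a0 != 0")
        if self.b0 != 0:
            raise LandmarkError("midline is vertical by definition (b0 = 0)")

    @property
    def x0(self) -> float:
        return -self.c0 / self.a0

    @classmethod
    def at(cls, x0: float) -> "MidLine":
        return cls(a0=1.0, c0=-float(x0))


@dataclass
class KeypointSet:
    """All landmark points of one radiograph (pixel coordinates)."""

    A1: Optional[Point] = None
    A2: Optional[Point] = None
    B1: Optional[Point] = None
    B2: Optional[Point] = None
    C1: Optional[Point] = None
    C2: Optional[Point] = None
    C1p: Optional[Point] = None
    C2p: Optional[Point] = None
    D1: Optional[Point] = None
    D2p: Optional[Point] = None
    D3p: Optional[Point] = None
    E1: Optional[Point] = None
    E2: Optional[Point] = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "A1", "A2", "B1", "B2", "C1", "C2", "C1p", "C2p", "D1", "D2p", "D3p", "E1", "E2")}


def point_line_distance(p: Point, a: float, b: float, c: float) -> float:
    """Perpendicular Euclidean distance from ``p`` to the line a*x + b*y + c = 0."""
    if a == 0 and b == 0:
        raise LandmarkError("degenerate line coefficients (a, b) = (0, 0)")
    return abs(a * p.x + b * p.y + c) / math.hypot(a, b)


def _is_right(side: str) -> bool:
    return side == PATIENT_RIGHT


def locate_apex(contour: Contour) -> Point:
    """Topmost boundary point; ties broken toward the medial side."""
    if _is_right(contour.side):
        return min(contour.points, key=lambda p: (p.y, -p.x))
    return min(contour.points, key=lambda p: (p.y, p.x))


def locate_costophrenic_angle(contour: Contour) -> Point:
    """Lowest boundary point in the lateral half of the lung's x-span.

    Restricting to the lateral half keeps a low-hanging cardiac
    silhouette from stealing the candidate.
    """
    xs = [p.x for p in contour.points]
    x_mid = (min(xs) + max(xs)) / 2.0
    if _is_right(contour.side):
        cands = [p for p in contour.points if p.x <= x_mid]
        return max(cands, key=lambda p: (p.y, -p.x))  # tie: lateral = small x
    cands = [p for p in contour.points if p.x >= x_mid]
    return max(cands, key=lambda p: (p.y, p.x))  # tie: lateral = large x


def _chord(p1: Point, p2: Point) -> Tuple[float, float, float]:
    """Line coefficients (a, b, c) of the chord through two points."""
    a = float(p2.y - p1.y)
    b = float(p1.x - p2.x)
    c = -(a * p1.x + b * p1.y)
    return a, b, c


def locate_cardiophrenic_angle(contour: Contour, apex: Point, costo: Point) -> Point:
    """Farthest point from the apex-costophrenic chord, on the medial arc.

    The search is restricted to the medial apex-to-costophrenic arc; an
    unrestricted argmax could land on the lateral chest wall.  Ties go to
    the inferior-most (largest y) candidate.
    """
    if apex == costo:
        raise LandmarkError("apex and costophrenic angle coincide")
    arc = contour_arc(contour, apex, costo, pick="medial")
    a, b, c = _chord(apex, costo)
    best = max(arc, key=lambda p: (point_line_distance(p, a, b, c), p.y))
    if point_line_distance(best, a, b, c) == 0.0:
        raise LandmarkError("no cardiophrenic angle: medial arc is collinear with the chord")
    return best


def locate_diaphragm_top(contour: Contour, costo: Point, cardio: Point) -> Point:
    """Highest point of the diaphragm arc between the costophrenic and
    cardiophrenic angles (the inferior arc, i.e. the one avoiding the apex).

    Ties break toward the lateral side (smaller x for patient-right).
    """
    apex = locate_apex(contour)
    arc_a, arc_b = _both_arcs(contour, costo, cardio)
    in_a = apex in arc_a
    in_b = apex in arc_b
    if in_a and in_b:
        # apex can only be an endpoint of both; the diaphragm arc is the
        # one where it appears as endpoint only if degenerate
        raise LandmarkError("cannot isolate the inferior costophrenic-cardiophrenic arc")
    arc = arc_b if in_a else arc_a
    if not arc:
        raise LandmarkError("empty diaphragm arc")
    if _is_right(contour.side):
        return min(arc, key=lambda p: (p.y, p.x))
    return min(arc, key=lambda p: (p.y, -p.x))


def locate_thoracic_extremes(right_contour: Contour, left_contour: Contour) -> Tuple[Point, Point]:
    """Thoracic inner-edge extremes D2'/D3'.

    D2' is the minimum-x boundary point of the patient-right lung, D3'
    the maximum-x point of the patient-left lung; ties break to smaller y.
    """
    d2p = min(right_contour.points, key=lambda p: (p.x, p.y))
    d3p = max(left_contour.points, key=lambda p: (p.x, -p.y))
    return d2p, d3p


def termination_point(
    profile: MedialProfile,
    cardio: Point,
    apex: Point,
    mode: str = "fraction",
    f: float = 0.5,
) -> Point:
    """Superior termination point (C1'/C2') of the cardiac-margin search.

    ``mode='fraction'``: the target row is the fraction ``f`` of the
    apex-to-cardiophrenic-angle height above the cardiophrenic angle:
    ``y_term = y(cardio) - round_half_up(f * (y(cardio) - y(apex)))``.
    ``mode='row'``: ``f`` is the absolute target row.  If the target row
    is not populated, the nearest populated row below it (toward the
    cardiophrenic angle) is used.  The result is strictly superior to the
    cardiophrenic angle.
    """
    if mode == "fraction":
        if not (0 < f < 1):
            raise LandmarkError(f"fraction must be in (0, 1), got {f}")
        if not apex.y < cardio.y:
            raise LandmarkError("apex must be superior to the cardiophrenic angle")
        y_term = cardio.y - int(math.floor(f * (cardio.y - apex.y) + 0.5))
    elif mode == "row":
        y_term = int(f)
    else:
        raise LandmarkError(f"unknown termination mode {mode!r}")

    y_term = min(y_term, cardio.y - 1)  # the result must stay superior to the angle
    populated = {r[0] for r in profile.rows}
    y = y_term
    while y < cardio.y and y not in populated:
        y += 1
    if y >= cardio.y:
        raise LandmarkError("no populated profile row between apex and cardiophrenic angle")
    return profile.medial_point(y)


def locate_heart_border(
    profile: MedialProfile,
    cardio: Point,
    termination: Point,
    midline: MidLine,
) -> Point:
    """Heart-border point E on the medial edge between termination and
    cardiophrenic rows: the candidate of maximum perpendicular distance
    to the vertical midline; ties go to the inferior-most candidate.

    All candidates must lie strictly on one side of the midline (the
    midline runs between the lungs), which makes the result independent
    of the midline's exact position.
    """
    if not termination.y < cardio.y:
        raise LandmarkError("termination point must be superior to the cardiophrenic angle")
    cands = [Point(xm, y) for y, xm, _ in profile.rows if termination.y <= y <= cardio.y]
    if not cands:
        raise LandmarkError("empty cardiac-margin candidate segment")
    x0 = midline.x0
    if not (all(p.x < x0 for p in cands) or all(p.x > x0 for p in cands)):
        raise LandmarkError("midline inside lung: candidates straddle the midline")
    return max(cands, key=lambda p: (abs(p.x - x0), p.y))
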
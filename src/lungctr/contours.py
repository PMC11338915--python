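"""Boundary tracing and per-row edge profiles of a single lung.

The boundary is traced on-pixel: a boundary pixel is a foreground pixel
with at least one background 4-neighbor (the image border counts as
background).  Tracing uses Moore-neighborhood following, clockwise in
image coordinates, starting from the topmost-then-leftmost boundary
pixel, with Jacob's stopping criterion.  Keeping the contour on mask
pixels (rather than on inter-pixel cracks) means every landmark the
later stages locate is an actual mask pixel, and all geometry stays in
integer pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .errors import ContourError
from .mask_io import BinaryMask, Point

PATIENT_RIGHT = "patient_right"
PATIENT_LEFT = "patient_left"

# 8-neighborhood in clockwise order for image coordinates (y down)
_RING = ((1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1))
_RING_INDEX = {d: i for i, d in enumerate(_RING)}


@dataclass
class Contour:
    """Ordered closed boundary path of one lung.

    Consecutive points (cyclically) are 8-adjacent; the path visits every
    boundary pixel of the component at least once.  Orientation is
    clockwise in image coordinates; the start point is the topmost, then
    leftmost boundary pixel.
    """

    points: List[Point]
    side: str

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class MedialProfile:
    """Per-row medial/lateral edge columns of one lung.

    One entry ``(y, x_medial, x_lateral)`` per row intersecting the lung.
    For the patient-right lung the medial edge is the row's maximum x
    (toward the image center) and the lateral edge the minimum; for the
    patient-left lung the roles are reversed.
    """

    rows: List[Tuple[int, int, int]]
    side: str

    def medial_point(self, y: int) -> Point:
        for ry, xm, _ in self.rows:
            if ry == y:
                return Point(xm, ry)
        raise ContourError(f"no profile entry at row {y}")

    def row_map(self) -> dict:
        return {ry: (xm, xl) for ry, xm, xl in self.rows}


def boundary_pixel_set(grid: np.ndarray) -> np.ndarray:
    """Boolean grid of boundary pixels: foreground with a background 4-neighbor."""
    g = np.asarray(grid, dtype=bool)
    padded = np.pad(g, 1, constant_values=False)
    n4_all_fg = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return g & ~n4_all_fg


def trace_boundary(lung: BinaryMask, side: str) -> Contour:
    """Trace the closed outer boundary of a single hole-free component."""
    from scipy import ndimage

    if side not in (PATIENT_RIGHT, PATIENT_LEFT):
        raise ContourError(f"unknown side {side!r}")
    g = lung.grid
    if not g.any():
        raise ContourError("empty mask")
    _, n = ndimage.label(g, structure=np.ones((3, 3), dtype=bool))
    if n != 1:
        raise ContourError(f"expected a single component, found {n}; run lung-field selection first")

    ys, xs = np.nonzero(g)
    i0 = np.lexsort((xs, ys))[0]  # topmost, then leftmost
    start = Point(int(xs[i0]), int(ys[i0]))

    h, w = g.shape

    def fg(x: int, y: int) -> bool:
        return 0 <= x < w and 0 <= y < h and g[y, x]

    # backtrack starts one step west of the start pixel (background,
    # since the start is the leftmost foreground pixel of the top row).
    # The trace is a deterministic map on (pixel, backtrack) states; it
    # enters a cycle that walks the complete outer boundary.  We iterate
    # until a state repeats and keep exactly that cycle, which is robust
    # even when the synthetic initial state lies off the cycle.
    points: List[Point] = [start]
    cur = start
    back_dir = (-1, 0)  # direction from cur toward the backtrack pixel
    seen = {(cur, back_dir): 0}
    limit = 8 * (h * w) + 16

    cycle_start = 0
    while True:
        limit -= 1
        if limit < 0:  # pragma: no cover - safety net
            raise ContourError("boundary tracing did not terminate")
        k = _RING_INDEX[back_dir]
        nxt = None
        for step in range(1, 9):
            d = _RING[(k + step) % 8]
            px, py = cur.x + d[0], cur.y + d[1]
            if fg(px, py):
                nxt = (Point(px, py), step)
                break
        if nxt is None:
            return Contour(points=points, side=side)  # isolated single pixel
        new_cur, step = nxt
        # backtrack for the new pixel: the last background neighbor examined
        # (the ring position just before the chosen one), as a direction
        prev = _RING[(k + step - 1) % 8]
        bx, by = cur.x + prev[0], cur.y + prev[1]
        back_dir = (bx - new_cur.x, by - new_cur.y)
        cur = new_cur
        state = (cur, back_dir)
        if state in seen:
            cycle_start = seen[state]
            break
        seen[state] = len(points)
        points.append(cur)

    cycle = points[cycle_start:]
    # canonical start: topmost, then leftmost pixel of the cycle
    anchor = min(range(len(cycle)), key=lambda i: (cycle[i].y, cycle[i].x))
    return Contour(points=cycle[anchor:] + cycle[:anchor], side=side)


def medial_profile(contour: Contour) -> MedialProfile:
    """Row-wise medial/lateral edge columns derived from the contour."""
    per_row: dict = {}
    for p in contour.points:
        lo, hi = per_row.get(p.y, (p.x, p.x))
        per_row[p.y] = (min(lo, p.x), max(hi, p.x))
    rows = []
    for y in sorted(per_row):
        lo, hi = per_row[y]
        if contour.side == PATIENT_RIGHT:
            rows.append((y, hi, lo))  # medial = max x
        else:
            rows.append((y, lo, hi))  # medial = min x
    return MedialProfile(rows=rows, side=contour.side)


def _both_arcs(contour: Contour, p_from: Point, p_to: Point):
    """The two directed arcs from ``p_from`` to ``p_to`` along the contour."""
    pts = contour.points
    try:
        i = pts.index(p_from)
        j = pts.index(p_to)
    except ValueError as exc:
        raise ContourError(f"point not on contour: {exc}") from exc
    if p_from == p_to:
        raise ContourError("degenerate arc")
    if i <= j:
        fwd = pts[i : j + 1]
        bwd = pts[j:] + pts[: i + 1]
    else:
        fwd = pts[i:] + pts[: j + 1]
        bwd = pts[j : i + 1]
    return fwd, list(reversed(bwd))


def contour_arc(contour: Contour, p_from: Point, p_to: Point, pick: str) -> List[Point]:
    """Of the two arcs between two contour points, pick the medial or lateral one.

    "Medial" is the arc whose mean x lies toward the image center given
    the contour's patient side (larger mean x for patient-right, smaller
    for patient-left); "lateral" is the other arc.  The returned arc runs
    from ``p_from`` to ``p_to`` inclusive.
    """
    if pick not in ("medial", "lateral"):
        raise ContourError(f"unknown arc pick {pick!r}")
    a, b = _both_arcs(contour, p_from, p_to)
    mean_a = sum(p.x for p in a) / len(a)
    mean_b = sum(p.x for p in b) / len(b)
    if contour.side == PATIENT_RIGHT:
        medial_arc = a if mean_a >= mean_b else b
    else:
        medial_arc = a if mean_a <= mean_b else b
    lateral_arc = b if medial_arc is a else a
    return medial_arc if pick == "medial" else lateral_arc
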
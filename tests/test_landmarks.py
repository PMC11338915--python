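import math

import numpy as np
import pytest

from lungctr.contours import (
    Contour,
    MedialProfile,
    PATIENT_LEFT,
    PATIENT_RIGHT,
    medial_profile,
    trace_boundary,
)
from lungctr.errors import LandmarkError
from lungctr.landmarks import (
    MidLine,
    locate_apex,
    locate_cardiophrenic_angle,
    locate_costophrenic_angle,
    locate_diaphragm_top,
    locate_heart_border,
    locate_thoracic_extremes,
    point_line_distance,
    termination_point,
)
from lungctr.lungfields import label_components, select_lung_fields
from lungctr.mask_io import BinaryMask, Point
from lungctr.phantom import oracle_keypoints


def _rect_contour(side, x0=10, x1=20, y0=5, y1=8):
    g = np.zeros((y1 + 3, x1 + 3), dtype=bool)
    g[y0 : y1 + 1, x0 : x1 + 1] = True
    return trace_boundary(BinaryMask(g), side)


@pytest.mark.parametrize(
    "a,b,c,p,expected",
    [
        (1, 0, -100, (40, 200), 60.0),
        (3, 4, -10, (2, 1), 0.0),
        (3, 4, 0, (4, 3), 4.8),
    ],
)
def test_point_line_distance(a, b, c, p, expected):
    assert point_line_distance(Point(*p), a, b, c) == pytest.approx(expected)


def test_point_line_distance_degenerate():
    with pytest.raises(LandmarkError):
        point_line_distance(Point(0, 0), 0, 0, 5)


@pytest.mark.parametrize("side,expected", [(PATIENT_RIGHT, (20, 5)), (PATIENT_LEFT, (10, 5))])
def test_apex_tie_breaks_medial(side, expected):
    assert locate_apex(_rect_contour(side)) == Point(*expected)


@pytest.mark.parametrize("side,expected", [(PATIENT_RIGHT, (10, 8)), (PATIENT_LEFT, (20, 8))])
def test_costophrenic_lowest_lateral_corner(side, expected):
    assert locate_costophrenic_angle(_rect_contour(side)) == Point(*expected)


def test_cardiophrenic_right_angle_corner():
    # L-shaped arc: the corner is farthest from the chord (10,0)-(0,30)
    arc = [Point(10, 0), Point(10, 10), Point(10, 20), Point(10, 30),
           Point(5, 30), Point(0, 30)]
    a, b, c = 30.0, 10.0, -300.0  # chord through (10,0) and (0,30)
    best = max(arc, key=lambda p: (point_line_distance(p, a, b, c), p.y))
    assert best == Point(10, 30)
    assert point_line_distance(best, a, b, c) == pytest.approx(30 / math.sqrt(10))


def test_cardiophrenic_collinear_errors():
    # a thin horizontal bar: the medial arc degenerates onto the chord
    g = np.zeros((4, 12), dtype=bool)
    g[1, 1:11] = True
    c = trace_boundary(BinaryMask(g), PATIENT_RIGHT)
    apex, costo = Point(10, 1), Point(1, 1)
    with pytest.raises(LandmarkError, match="cardiophrenic"):
        locate_cardiophrenic_angle(c, apex, costo)


def test_cardiophrenic_on_phantom_matches_truth(small_phantom):
    mask, truth = small_phantom
    pair = select_lung_fields(label_components(mask))
    c = trace_boundary(pair.right, PATIENT_RIGHT)
    apex = locate_apex(c)
    costo = locate_costophrenic_angle(c)
    got = locate_cardiophrenic_angle(c, apex, costo)
    t = truth.keypoints.C1
    assert abs(got.x - t.x) <= 2 and abs(got.y - t.y) <= 2


def test_diaphragm_top_flat_bottom_rectangle():
    c = _rect_contour(PATIENT_RIGHT)
    got = locate_diaphragm_top(c, Point(10, 8), Point(20, 8))
    assert got.y == 8  # flat diaphragm: bottom row, tie rule picks small x
    assert got == Point(10, 8)


def test_diaphragm_arch_raised_by_five(small_phantom):
    from lungctr.phantom import PhantomSpec, generate_phantom

    base = PhantomSpec(width=256, height=256, thorax_width=200, heart_width=90,
                       apex_y=40, base_y=216, diaphragm_arch=20, seed=2)
    raised = PhantomSpec(width=256, height=256, thorax_width=200, heart_width=90,
                         apex_y=40, base_y=216, diaphragm_arch=25, seed=2)
    _, t0 = generate_phantom(base)
    _, t1 = generate_phantom(raised)
    assert t0.keypoints.D1.y - t1.keypoints.D1.y == 5


def test_thoracic_extremes_rectangles():
    g = np.zeros((40, 500), dtype=bool)
    g[5:35, 50:201] = True
    g[5:35, 300:451] = True
    pair = select_lung_fields(label_components(BinaryMask(g)))
    cr = trace_boundary(pair.right, PATIENT_RIGHT)
    cl = trace_boundary(pair.left, PATIENT_LEFT)
    d2p, d3p = locate_thoracic_extremes(cr, cl)
    assert d2p.x == 50 and d3p.x == 450
    assert d2p.y == 5 and d3p.y == 5  # tie to smaller y


def test_thoracic_extremes_mirror(small_phantom):
    mask, _ = small_phantom
    w = mask.width
    pair = select_lung_fields(label_components(mask))
    d2p, d3p = locate_thoracic_extremes(
        trace_boundary(pair.right, PATIENT_RIGHT), trace_boundary(pair.left, PATIENT_LEFT))
    flipped = BinaryMask(mask.grid[:, ::-1])
    fpair = select_lung_fields(label_components(flipped))
    f2p, f3p = locate_thoracic_extremes(
        trace_boundary(fpair.right, PATIENT_RIGHT), trace_boundary(fpair.left, PATIENT_LEFT))
    assert f2p.x == w - 1 - d3p.x and f3p.x == w - 1 - d2p.x


def test_termination_row_arithmetic():
    rows = [(y, 230 - (y % 3), 100) for y in range(80, 380)]
    prof = MedialProfile(rows=rows, side=PATIENT_RIGHT)
    got = termination_point(prof, cardio=Point(230, 380), apex=Point(180, 80), f=0.5)
    assert got.y == 230
    assert got.x == 230 - (230 % 3)


def test_termination_f_to_zero_limit():
    rows = [(y, 200, 100) for y in range(10, 50)]
    prof = MedialProfile(rows=rows, side=PATIENT_RIGHT)
    got = termination_point(prof, cardio=Point(200, 40), apex=Point(200, 10), f=1e-9)
    assert got.y == 39  # immediately superior to the cardiophrenic angle


def test_termination_unpopulated_row_errors():
    prof = MedialProfile(rows=[(50, 200, 100)], side=PATIENT_RIGHT)
    with pytest.raises(LandmarkError, match="populated"):
        termination_point(prof, cardio=Point(200, 40), apex=Point(200, 10), f=0.5)


def test_heart_border_extremal_x_and_ties():
    rows = [(285, 228, 0), (290, 225, 0), (295, 228, 0), (300, 230, 0)]
    prof = MedialProfile(rows=rows, side=PATIENT_RIGHT)
    mid = MidLine.at(256)
    got = locate_heart_border(prof, cardio=Point(230, 300), termination=Point(228, 285), midline=mid)
    assert got == Point(225, 290)
    assert abs(got.x - mid.x0) == 31
    # tie: two rows at the same extremal x -> inferior-most wins
    prof2 = MedialProfile(rows=[(280, 225, 0), (290, 225, 0)], side=PATIENT_RIGHT)
    got2 = locate_heart_border(prof2, cardio=Point(230, 300), termination=Point(225, 280), midline=mid)
    assert got2 == Point(225, 290)


def test_heart_border_straddling_midline_errors():
    prof = MedialProfile(rows=[(10, 100, 0), (11, 300, 0)], side=PATIENT_RIGHT)
    with pytest.raises(LandmarkError, match="midline"):
        locate_heart_border(prof, cardio=Point(100, 12), termination=Point(100, 10),
                            midline=MidLine.at(256))


def test_heart_border_midline_invariance(default_phantom):
    """Any midline strictly medial to all candidates gives the same point."""
    mask, truth = default_phantom
    pair = select_lung_fields(label_components(mask))
    c = trace_boundary(pair.right, PATIENT_RIGHT)
    prof = medial_profile(c)
    kp = oracle_keypoints(mask)
    results = {
        locate_heart_border(prof, kp.C1, kp.C1p, MidLine.at(x0)) for x0 in (240, 256, 270)
    }
    assert results == {kp.E1}


def test_midline_type_validation():
    with pytest.raises(LandmarkError):
        MidLine(a0=0.0, c0=-5.0)
    assert MidLine.at(100).x0 == 100.0


def test_landmarks_translation_equivariance(small_phantom):
    from lungctr.ctr_core import run_pipeline

    mask, _ = small_phantom
    kp, _ = run_pipeline(mask)
    dy, dx = 7, 11
    padded = np.zeros((mask.height + 20, mask.width + 20), dtype=bool)
    padded[dy : dy + mask.height, dx : dx + mask.width] = mask.grid
    kp2, _ = run_pipeline(BinaryMask(padded))
    for name, p in kp.as_dict().items():
        q = getattr(kp2, name)
        assert (q.x - p.x, q.y - p.y) == (dx, dy)
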
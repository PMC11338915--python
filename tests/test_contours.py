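import numpy as np
import pytest
from scipy import ndimage

from lungctr.contours import (
    PATIENT_LEFT,
    PATIENT_RIGHT,
    boundary_pixel_set,
    contour_arc,
    medial_profile,
    trace_boundary,
)
from lungctr.errors import ContourError
from lungctr.lungfields import label_components, select_lung_fields
from lungctr.mask_io import BinaryMask, Point


def _mask(grid):
    return BinaryMask(np.asarray(grid, dtype=bool))


def _brute_boundary(grid):
    """Oracle: foreground pixels with a background 4-neighbor (border = background)."""
    g = np.asarray(grid, dtype=bool)
    h, w = g.shape
    out = set()
    for y, x in zip(*np.nonzero(g)):
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ny, nx = y + dy, x + dx
            if not (0 <= ny < h and 0 <= nx < w) or not g[ny, nx]:
                out.add((int(x), int(y)))
                break
    return out


def test_single_pixel_contour():
    g = np.zeros((3, 3), dtype=bool)
    g[1, 1] = True
    c = trace_boundary(_mask(g), PATIENT_RIGHT)
    assert c.points == [Point(1, 1)]


def test_filled_square_perimeter_only():
    g = np.zeros((5, 5), dtype=bool)
    g[1:4, 1:4] = True
    c = trace_boundary(_mask(g), PATIENT_RIGHT)
    assert set((p.x, p.y) for p in c.points) == _brute_boundary(g)
    assert Point(2, 2) not in c.points  # center excluded
    assert len(c.points) == 8
    assert c.points[0] == Point(1, 1)  # topmost-leftmost start


def test_contour_consecutive_points_8_adjacent(small_phantom):
    mask, _ = small_phantom
    pair = select_lung_fields(label_components(mask))
    for lung, side in ((pair.right, PATIENT_RIGHT), (pair.left, PATIENT_LEFT)):
        c = trace_boundary(lung, side)
        pts = c.points
        for a, b in zip(pts, pts[1:] + pts[:1]):
            assert max(abs(a.x - b.x), abs(a.y - b.y)) == 1
        assert pts[0] == min(pts, key=lambda p: (p.y, p.x))


def test_contour_covers_boundary_set(small_phantom):
    mask, _ = small_phantom
    pair = select_lung_fields(label_components(mask))
    for lung, side in ((pair.right, PATIENT_RIGHT), (pair.left, PATIENT_LEFT)):
        c = trace_boundary(lung, side)
        assert set((p.x, p.y) for p in c.points) == _brute_boundary(lung.grid)


def test_fill_of_contour_reproduces_component(small_phantom):
    mask, _ = small_phantom
    pair = select_lung_fields(label_components(mask))
    c = trace_boundary(pair.right, PATIENT_RIGHT)
    edge = np.zeros_like(pair.right.grid)
    for p in c.points:
        edge[p.y, p.x] = True
    assert np.array_equal(ndimage.binary_fill_holes(edge), pair.right.grid)


def test_multi_component_rejected():
    g = np.zeros((10, 10), dtype=bool)
    g[1:3, 1:3] = True
    g[6:8, 6:8] = True
    with pytest.raises(ContourError, match="single component"):
        trace_boundary(_mask(g), PATIENT_RIGHT)
    with pytest.raises(ContourError, match="empty"):
        trace_boundary(_mask(np.zeros((4, 4))), PATIENT_RIGHT)


@pytest.mark.parametrize("side,medial,lateral", [
    (PATIENT_RIGHT, 20, 10),
    (PATIENT_LEFT, 10, 20),
])
def test_rectangle_profile_sides(side, medial, lateral):
    g = np.zeros((12, 25), dtype=bool)
    g[5:9, 10:21] = True  # x in [10, 20], y in [5, 8]
    prof = medial_profile(trace_boundary(_mask(g), side))
    assert [r[0] for r in prof.rows] == [5, 6, 7, 8]
    assert all(xm == medial and xl == lateral for _, xm, xl in prof.rows)


def test_profile_matches_raster_row_scans(small_phantom):
    mask, _ = small_phantom
    pair = select_lung_fields(label_components(mask))
    prof = medial_profile(trace_boundary(pair.right, PATIENT_RIGHT))
    for y, xm, xl in prof.rows:
        xs = np.nonzero(pair.right.grid[y])[0]
        assert xm == xs.max() and xl == xs.min()


def test_profile_mirror_property(small_phantom):
    mask, _ = small_phantom
    pair = select_lung_fields(label_components(mask))
    w = mask.width
    prof_r = medial_profile(trace_boundary(pair.right, PATIENT_RIGHT))
    flipped = BinaryMask(pair.right.grid[:, ::-1])
    prof_f = medial_profile(trace_boundary(flipped, PATIENT_LEFT))
    assert [(y, w - 1 - xm, w - 1 - xl) for y, xm, xl in prof_r.rows] == prof_f.rows


def test_square_arc_selection():
    g = np.zeros((8, 8), dtype=bool)
    g[1:5, 1:5] = True
    c = trace_boundary(_mask(g), PATIENT_RIGHT)
    arc = contour_arc(c, Point(1, 1), Point(4, 4), pick="medial")
    assert all(p in arc for p in (Point(4, 1), Point(4, 2)))  # passes max-x side
    lat = contour_arc(c, Point(1, 1), Point(4, 4), pick="lateral")
    assert Point(1, 4) in lat


def test_adjacent_points_direct_hop():
    g = np.zeros((8, 8), dtype=bool)
    g[1:5, 1:5] = True
    c = trace_boundary(_mask(g), PATIENT_RIGHT)
    a, b = c.points[0], c.points[1]
    med = contour_arc(c, a, b, pick="medial")
    lat = contour_arc(c, a, b, pick="lateral")
    assert [a, b] in (med, lat)  # one of the two arcs is the direct hop


def test_arcs_partition_contour(small_phantom):
    mask, _ = small_phantom
    pair = select_lung_fields(label_components(mask))
    c = trace_boundary(pair.right, PATIENT_RIGHT)
    a, b = c.points[0], c.points[len(c.points) // 2]
    med = contour_arc(c, a, b, pick="medial")
    lat = contour_arc(c, a, b, pick="lateral")
    assert set(med) & set(lat) == {a, b}
    assert set(med) | set(lat) == set(c.points)


def test_degenerate_arc_errors(small_phantom):
    mask, _ = small_phantom
    pair = select_lung_fields(label_components(mask))
    c = trace_boundary(pair.right, PATIENT_RIGHT)
    with pytest.raises(ContourError, match="degenerate"):
        contour_arc(c, c.points[0], c.points[0], pick="medial")
    with pytest.raises(ContourError, match="not on contour"):
        contour_arc(c, Point(0, 0), c.points[1], pick="medial")


def test_boundary_pixel_set_matches_brute_force(rng):
    g = ndimage.binary_closing(rng.random((40, 40)) > 0.45)
    got = boundary_pixel_set(g)
    assert set(map(tuple, np.argwhere(got)[:, ::-1])) == _brute_boundary(g)
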
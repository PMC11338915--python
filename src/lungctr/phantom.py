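"""Synthetic lung-pair phantoms with oracle-derived ground truth.

A phantom emulates the output of a chest-radiograph lung-field
segmenter: two lung-shaped foreground components on a 512x512 canvas,
each with a cardiac indentation on its medial border.  Every boundary is
an analytic curve, so the true landmark positions are known by
construction; the recorded ground truth, however, is recomputed from the
*rasterized* mask by brute-force pixel scans (:func:`oracle_keypoints`),
so truth and detection share the same pixel grid and no rasterization
rounding can separate them.

Each lung outline is a closed curve assembled from

* a lateral elliptical arc from the apex out to the chest wall and down
  to the costophrenic corner,
* a diaphragm arc with an interior peak between the costophrenic and
  cardiophrenic corners,
* a parabolic cardiac bulge whose extremal column realizes the
  specified heart border, and
* a near-vertical mediastinal segment back up to the apex.

Anatomy note baked into the defaults: roughly one-third of the heart
lies to the patient-right of the midline and two-thirds to the left, so
``heart_right_frac`` defaults to 1/3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as sk_polygon, polygon_perimeter as sk_polygon_perimeter

from .errors import LungCTRError, MaskInputError
from .landmarks import KeypointSet
from .mask_io import BinaryMask, Point
from .util import round_half_up


@dataclass
class PhantomSpec:
    """Parameters of a synthetic lung-pair mask.

    Distances are pixels.  ``thorax_width`` separates the two lateral
    lung extremes (the true thoracic diameter); ``heart_width`` separates
    the two cardiac-bulge extremes (the true heart diameter).
    """

    width: int = 512
    height: int = 512
    thorax_width: int = 400
    heart_width: int = 180
    heart_right_frac: float = 1.0 / 3.0
    apex_y: int = 80
    base_y: int = 432
    diaphragm_arch: int = 40
    bulge_height_frac: float = 0.25
    jitter_px: float = 0.0
    n_spurious: int = 0
    n_holes: int = 0
    seed: int = 0

    def validate(self) -> None:
        problems: List[str] = []
        cx = self.width / 2.0
        if self.heart_width >= self.thorax_width:
            problems.append("heart_width must be smaller than thorax_width")
        if not (0 < self.heart_right_frac < 1):
            problems.append("heart_right_frac must be in (0, 1)")
        if not (2 <= self.apex_y < self.base_y <= self.height - 3):
            problems.append("vertical extent [apex_y, base_y] must fit the canvas with 2 px margin")
        if cx - self.thorax_width / 2.0 < 2 or cx + self.thorax_width / 2.0 > self.width - 3:
            problems.append("thorax_width must fit the canvas with 2 px margin")
        reach = self._gap() + self._corner_offset() + 2
        if self.heart_width * self.heart_right_frac <= reach:
            problems.append("patient-right heart extent must exceed the cardiophrenic-corner reach")
        if self.heart_width * (1 - self.heart_right_frac) <= reach:
            problems.append("patient-left heart extent must exceed the cardiophrenic-corner reach")
        if not (0.05 <= self.bulge_height_frac <= 0.35):
            problems.append("bulge_height_frac must be in [0.05, 0.35]")
        if self.diaphragm_arch < 0 or self.diaphragm_arch > (self.base_y - self.apex_y) / 3:
            problems.append("diaphragm_arch must be non-negative and below a third of the lung height")
        if self.jitter_px < 0 or self.jitter_px > 4:
            problems.append("jitter_px must be in [0, 4]")
        if problems:
            raise LungCTRError("infeasible phantom spec: " + "; ".join(problems))

    def _gap(self) -> float:
        # mediastinal half-gap between lung and canvas center
        return max(6.0, 0.05 * self.thorax_width)

    def _corner_offset(self) -> float:
        # lateral offset of the cardiophrenic corner from the mediastinum
        return max(4.0, 0.02 * self.width)


@dataclass
class PhantomTruth:
    """Oracle-scan ground truth of a phantom mask."""

    keypoints: KeypointSet
    dx1_true: int
    dx2_true: int
    ctr_true: float
    seed: int = 0


# ---------------------------------------------------------------------------
# analytic outline


def _lung_outline(spec: PhantomSpec, side: str) -> np.ndarray:
    """Densely sampled closed outline of one lung, as an (N, 2) array of
    (x, y) in continuous image coordinates."""
    cx = spec.width / 2.0
    s = -1.0 if side == "patient_right" else +1.0  # medial offsets applied as cx + s*offset
    gap = spec._gap()
    tw2 = spec.thorax_width / 2.0
    heart_off = spec.heart_width * (spec.heart_right_frac if s < 0 else 1 - spec.heart_right_frac)

    x_lat = cx + s * tw2
    x_medtop = cx + s * gap
    x_heart = cx + s * heart_off
    # the cardiophrenic corner sits close to the mediastinum (near the
    # midline), well medial of the cardiac bulge extremum
    x_cardio = cx + s * (gap + spec._corner_offset())
    x_apex = (x_lat + x_medtop) / 2.0

    y_apex = float(spec.apex_y)
    y_base = float(spec.base_y)
    h = y_base - y_apex
    y_mid = y_apex + 0.5 * h
    y_bulge = y_base - spec.bulge_height_frac * h
    y_bulge_top = y_base - (spec.bulge_height_frac + 0.2) * h

    pts: List[Tuple[float, float]] = []

    # lateral wall: apex -> widest point at mid-height -> costophrenic corner
    n = max(8, int(2 * h))
    for i in range(n + 1):
        y = y_apex + h * i / n
        if y <= y_mid:
            t = (y - y_apex) / (y_mid - y_apex)
            x = x_apex + (x_lat - x_apex) * math.sin(0.5 * math.pi * t)
        else:
            x = x_lat
        pts.append((x, y))

    # diaphragm: costophrenic corner -> arched -> cardiophrenic corner
    n = max(8, int(2 * abs(x_cardio - x_lat)))
    for i in range(1, n + 1):
        t = i / n
        x = x_lat + (x_cardio - x_lat) * t
        y = y_base - spec.diaphragm_arch * math.sin(math.pi * t)
        pts.append((x, y))

    # cardiac bulge: cardiophrenic corner -> extremum -> bulge top (two parabolas)
    n = max(8, int(2 * (y_base - y_bulge_top)))
    k_low = (x_cardio - x_heart) / (y_base - y_bulge) ** 2
    k_high = (x_medtop - x_heart) / (y_bulge_top - y_bulge) ** 2
    for i in range(1, n + 1):
        y = y_base + (y_bulge_top - y_base) * i / n
        k = k_low if y >= y_bulge else k_high
        x = x_heart + k * (y - y_bulge) ** 2
        pts.append((x, y))

    # mediastinal segment: bulge top -> apex
    n = max(8, int(2 * (y_bulge_top - y_apex)))
    for i in range(1, n):
        t = i / n
        pts.append((x_medtop + (x_apex - x_medtop) * t, y_bulge_top + (y_apex - y_bulge_top) * t))

    return np.asarray(pts, dtype=float)


def _apply_jitter(outline: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency boundary noise along the outward normal, max |amplitude| px."""
    if amplitude <= 0:
        return outline
    n = len(outline)
    n_ctrl = max(8, n // 40)
    ctrl = rng.normal(size=n_ctrl + 1)
    ctrl[-1] = ctrl[0]  # periodic
    t = np.linspace(0, n_ctrl, n, endpoint=False)
    noise = np.interp(t, np.arange(n_ctrl + 1), ctrl)
    peak = np.max(np.abs(noise))
    if peak > 0:
        noise = noise / peak * amplitude
    tangent = np.roll(outline, -1, axis=0) - np.roll(outline, 1, axis=0)
    norm = np.hypot(tangent[:, 0], tangent[:, 1])
    norm[norm == 0] = 1.0
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]]) / norm[:, None]
    return outline + normal * noise[:, None]


def _rasterize(outline: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    grid = np.zeros(shape, dtype=bool)
    rr, cc = sk_polygon(outline[:, 1], outline[:, 0], shape=shape)
    grid[rr, cc] = True
    # scanline fill can drop thin wedge tips (e.g. the cardiophrenic
    # corner); drawing the outline itself keeps the shape connected
    rr, cc = sk_polygon_perimeter(outline[:, 1], outline[:, 0], shape=shape, clip=True)
    grid[rr, cc] = True
    return ndimage.binary_fill_holes(grid)


# ---------------------------------------------------------------------------
# brute-force oracle scans (independent of the contour-tracing pipeline)


def _boundary(grid: np.ndarray) -> np.ndarray:
    g = np.asarray(grid, dtype=bool)
    p = np.pad(g, 1, constant_values=False)
    interior = p[:-2, 1:-1] & p[2:, 1:-1] & p[1:-1, :-2] & p[1:-1, 2:]
    return g & ~interior


def _split_lungs(grid: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    labels, n = ndimage.label(grid, structure=np.ones((3, 3), dtype=bool))
    if n != 2:
        raise LungCTRError(f"oracle expects exactly 2 components, found {n}")
    filled = [ndimage.binary_fill_holes(labels == i) for i in (1, 2)]
    cx = [np.nonzero(f)[1].mean() for f in filled]
    if cx[0] < cx[1]:
        return filled[0], filled[1]
    return filled[1], filled[0]


def _scan_apex(bys: np.ndarray, bxs: np.ndarray, right: bool) -> Point:
    y = bys.min()
    xs = bxs[bys == y]
    return Point(int(xs.max() if right else xs.min()), int(y))


def _scan_costo(bys: np.ndarray, bxs: np.ndarray, right: bool) -> Point:
    x_mid = (bxs.min() + bxs.max()) / 2.0
    sel = bxs <= x_mid if right else bxs >= x_mid
    ys, xs = bys[sel], bxs[sel]
    y = ys.max()
    cand = xs[ys == y]
    return Point(int(cand.min() if right else cand.max()), int(y))


def _row_medial(grid: np.ndarray, right: bool) -> dict:
    """Per-row medial-extreme column of a lung raster (max x for patient-right)."""
    out = {}
    rows = np.nonzero(grid.any(axis=1))[0]
    for y in rows:
        xs = np.nonzero(grid[y])[0]
        out[int(y)] = int(xs.max() if right else xs.min())
    return out


def _scan_cardio(grid: np.ndarray, apex: Point, costo: Point, right: bool) -> Point:
    a = float(costo.y - apex.y)
    b = float(apex.x - costo.x)
    c = -(a * apex.x + b * apex.y)
    med = _row_medial(grid, right)
    # the medial arc from apex to costophrenic angle can dip below the
    # costophrenic row, so scan every row from the apex down
    best = None
    for y in range(apex.y, max(med) + 1):
        if y not in med:
            continue
        p = Point(med[y], y)
        score = (abs(a * p.x + b * p.y + c), p.y)
        if best is None or score > best[0]:
            best = (score, p)
    if best is None:
        raise LungCTRError("oracle found no cardiophrenic candidates")
    return best[1]


def _scan_diaphragm_top(grid: np.ndarray, costo: Point, cardio: Point, right: bool) -> Point:
    x_lo, x_hi = sorted((costo.x, cardio.x))
    best = None
    for x in range(x_lo, x_hi + 1):
        ys = np.nonzero(grid[:, x])[0]
        if ys.size == 0:
            continue
        y = int(ys.max())  # bottom edge of the lung in this column
        key = (y, x if right else -x)
        if best is None or key < best[0]:
            best = (key, Point(x, y))
    if best is None:
        raise LungCTRError("oracle found no diaphragm candidates")
    return best[1]


def _scan_termination(med: dict, cardio: Point, apex: Point, f: float) -> Point:
    y_term = cardio.y - int(math.floor(f * (cardio.y - apex.y) + 0.5))
    y_term = min(y_term, cardio.y - 1)
    y = y_term
    while y < cardio.y and y not in med:
        y += 1
    if y >= cardio.y:
        raise LungCTRError("oracle found no termination row")
    return Point(med[y], y)


def _scan_heart_border(med: dict, cardio: Point, term: Point, x0: float) -> Point:
    best = None
    for y in range(term.y, cardio.y + 1):
        if y not in med:
            continue
        p = Point(med[y], y)
        key = (abs(p.x - x0), p.y)
        if best is None or key > best[0]:
            best = (key, p)
    if best is None:
        raise LungCTRError("oracle found no heart-border candidates")
    return best[1]


def oracle_keypoints(mask: BinaryMask, cardiac_search_fraction: float = 0.5) -> KeypointSet:
    """All 13 landmarks by brute-force raster scans.

    Independent of the contour-tracing pipeline: works directly on the
    pixel grid with vectorized row/column scans.  Used for phantom
    ground truth and as the test oracle.
    """
    right, left = _split_lungs(mask.grid)
    kp = KeypointSet()

    br = _boundary(right)
    bl = _boundary(left)
    rys, rxs = np.nonzero(br)
    lys, lxs = np.nonzero(bl)

    kp.A1 = _scan_apex(rys, rxs, right=True)
    kp.A2 = _scan_apex(lys, lxs, right=False)
    kp.B1 = _scan_costo(rys, rxs, right=True)
    kp.B2 = _scan_costo(lys, lxs, right=False)
    kp.C1 = _scan_cardio(right, kp.A1, kp.B1, right=True)
    kp.C2 = _scan_cardio(left, kp.A2, kp.B2, right=False)
    kp.D1 = _scan_diaphragm_top(right, kp.B1, kp.C1, right=True)

    # thoracic extremes: global min/max column, tie to smaller row
    x2 = rxs.min()
    kp.D2p = Point(int(x2), int(rys[rxs == x2].min()))
    x3 = lxs.max()
    kp.D3p = Point(int(x3), int(lys[lxs == x3].min()))

    med_r = _row_medial(right, right=True)
    med_l = _row_medial(left, right=False)
    kp.C1p = _scan_termination(med_r, kp.C1, kp.A1, cardiac_search_fraction)
    kp.C2p = _scan_termination(med_l, kp.C2, kp.A2, cardiac_search_fraction)

    x0 = (kp.D2p.x + kp.D3p.x) / 2.0
    kp.E1 = _scan_heart_border(med_r, kp.C1, kp.C1p, x0)
    kp.E2 = _scan_heart_border(med_l, kp.C2, kp.C2p, x0)
    return kp


def oracle_truth(mask: BinaryMask, seed: int = 0, cardiac_search_fraction: float = 0.5) -> PhantomTruth:
    kp = oracle_keypoints(mask, cardiac_search_fraction)
    dx1 = abs(kp.E1.x - kp.E2.x)
    dx2 = abs(kp.D2p.x - kp.D3p.x)
    return PhantomTruth(keypoints=kp, dx1_true=dx1, dx2_true=dx2,
                        ctr_true=dx1 / dx2, seed=seed)


def random_phantom_spec(
    rng: np.random.Generator,
    sizes: Tuple[int, ...] = (192, 256, 384, 512),
    jitter_choices: Tuple[float, ...] = (0.0, 0.0, 0.0, 1.0, 2.0),
) -> PhantomSpec:
    """Draw a feasible random phantom spec covering the plausible range of
    lung proportions (thorax 50-85 % of the canvas, heart 28-60 % of the
    thorax, one-quarter to nearly one-half of the heart patient-right)."""
    for _ in range(64):
        size = int(rng.choice(sizes))
        tw = int(rng.integers(int(0.5 * size), int(0.85 * size)))
        hw = int(rng.integers(int(0.28 * tw), int(0.6 * tw)))
        spec = PhantomSpec(
            width=size,
            height=size,
            thorax_width=tw,
            heart_width=hw,
            heart_right_frac=float(rng.uniform(0.28, 0.45)),
            apex_y=int(rng.integers(int(0.08 * size), int(0.2 * size))),
            base_y=int(rng.integers(int(0.78 * size), int(0.92 * size))),
            diaphragm_arch=int(rng.integers(0, max(1, (size // 4) // 2))),
            bulge_height_frac=float(rng.uniform(0.1, 0.35)),
            jitter_px=float(rng.choice(jitter_choices)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        try:
            spec.validate()
        except LungCTRError:
            continue
        if spec.diaphragm_arch > (spec.base_y - spec.apex_y) / 3:
            continue
        return spec
    raise LungCTRError("failed to draw a feasible phantom spec")


# ---------------------------------------------------------------------------
# generation and perturbation


def generate_phantom(spec: PhantomSpec) -> Tuple[BinaryMask, PhantomTruth]:
    """Rasterize a phantom lung pair and compute its oracle ground truth.

    Ground truth is scanned from the clean raster (after boundary jitter,
    before spurious blobs and holes, which by construction must not
    change the truth).  Deterministic for a fixed spec.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    grid = np.zeros(shape, dtype=bool)
    for side in ("patient_right", "patient_left"):
        outline = _lung_outline(spec, side)
        outline = _apply_jitter(outline, spec.jitter_px, rng)
        grid |= _rasterize(outline, shape)

    clean = BinaryMask(grid)
    truth = oracle_truth(clean, seed=spec.seed)

    if spec.n_spurious or spec.n_holes:
        mask = perturb_mask(clean, spec.n_spurious, spec.n_holes, spec.seed)
    else:
        mask = clean
    return mask, truth


def perturb_mask(mask: BinaryMask, n_spurious: int, n_holes: int, seed: int) -> BinaryMask:
    """Seeded perturbation: small spurious blobs (area < 100 px, away from
    the lungs) and small interior holes (area < 50 px, >= 2 px inside each
    boundary).  Neither kind may change the pipeline's result."""
    labels, n = ndimage.label(mask.grid, structure=np.ones((3, 3), dtype=bool))
    if n != 2:
        raise LungCTRError(f"perturb_mask expects a 2-component mask, found {n}")
    rng = np.random.default_rng(seed)
    grid = mask.grid.copy()
    h, w = grid.shape

    keepout = ndimage.binary_dilation(grid, iterations=3)
    placed = 0
    for _ in range(200 * max(1, n_spurious)):
        if placed >= n_spurious:
            break
        r = int(rng.integers(2, 5))  # disk radius 2-4 -> area <= 49 < 100
        cy = int(rng.integers(r + 1, h - r - 1))
        cxp = int(rng.integers(r + 1, w - r - 1))
        yy, xx = np.ogrid[:h, :w]
        disk = (yy - cy) ** 2 + (xx - cxp) ** 2 <= r * r
        if not (keepout & ndimage.binary_dilation(disk, iterations=2)).any():
            grid |= disk
            keepout |= ndimage.binary_dilation(disk, iterations=3)
            placed += 1
    if placed < n_spurious:
        raise LungCTRError("could not place spurious blobs without touching the lungs")

    if n_holes:
        # distance to background: a hole must stay >= 2 px from the boundary
        dist = ndimage.distance_transform_edt(mask.grid)
        for lab in (1, 2):
            punched = 0
            cand = np.argwhere((labels == lab) & (dist >= 6))
            if cand.size == 0:
                raise LungCTRError("no interior room for holes")
            for _ in range(200 * n_holes):
                if punched >= n_holes:
                    break
                cy, cxp = cand[int(rng.integers(len(cand)))]
                r = int(rng.integers(1, 4))  # disk radius 1-3 -> area <= 29 < 50
                yy, xx = np.ogrid[:h, :w]
                disk = (yy - cy) ** 2 + (xx - cxp) ** 2 <= r * r
                if dist[disk].min() >= r + 2:
                    grid &= ~disk
                    punched += 1
            if punched < n_holes:
                raise LungCTRError("could not punch the requested interior holes")

    return BinaryMask(grid)
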
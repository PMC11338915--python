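"""Full pipeline assembly and the CTR arithmetic.

The cardiothoracic ratio is

    dx1 = |x(E1) - x(E2)|      heart maximum transverse diameter
    dx2 = |x(D2') - x(D3')|    thoracic maximum transverse diameter
    CTR = dx1 / dx2

Absolute differences make the result independent of which side is
subtracted.  The reporting midline x0 is placed at the thoracic center
(x(D2') + x(D3')) / 2; by the midline-invariance of the heart-border
search it cannot affect E1/E2 or the CTR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Tuple

from . import contours as ct
from . import landmarks as lm
from .errors import LandmarkError, LungCTRError, PipelineError
from .lungfields import label_components, select_lung_fields
from .mask_io import BinaryMask, Point
from .util import round_half_up


@dataclass
class RunConfig:
    """Tunable knobs of the pipeline, validated up front.

    threshold            binarization cut on 8-bit intensity (foreground > t)
    min_area_frac        smallest component kept, as a fraction of image area
    side_assignment      'centroid' (default) or 'area_paper_literal'
    cardiac_search_fraction  fraction of apex-to-cardiophrenic height at
                             which the cardiac-margin search terminates
    termination_mode     'fraction' or 'row'
    """

    threshold: int = 127
    min_area_frac: float = 0.005
    side_assignment: str = "centroid"
    cardiac_search_fraction: float = 0.5
    termination_mode: str = "fraction"

    def validate(self) -> None:
        if not (0 <= self.threshold <= 255):
            raise LungCTRError(f"threshold out of range: {self.threshold}")
        if not (0 <= self.min_area_frac < 1):
            raise LungCTRError(f"min_area_frac out of range: {self.min_area_frac}")
        if self.side_assignment not in ("centroid", "area_paper_literal"):
            raise LungCTRError(f"unknown side_assignment: {self.side_assignment}")
        if self.termination_mode == "fraction" and not (0 < self.cardiac_search_fraction < 1):
            raise LungCTRError(
                f"cardiac_search_fraction out of range: {self.cardiac_search_fraction}"
            )
        if self.termination_mode not in ("fraction", "row"):
            raise LungCTRError(f"unknown termination_mode: {self.termination_mode}")


@dataclass
class CTRResult:
    """Heart and thoracic transverse diameters (pixels) and their ratio."""

    dx1: int
    dx2: int
    ctr: float
    midline_x0: float

    @property
    def ctr_rounded(self) -> float:
        return round_half_up(self.ctr, 4)


def compute_ctr(kp: lm.KeypointSet) -> CTRResult:
    """CTR from a completed landmark set."""
    for name in ("E1", "E2", "D2p", "D3p"):
        if getattr(kp, name) is None:
            raise LandmarkError(f"landmark {name} missing; cannot compute CTR")
    dx1 = abs(kp.E1.x - kp.E2.x)
    dx2 = abs(kp.D2p.x - kp.D3p.x)
    if dx2 == 0:
        raise LandmarkError("degenerate thorax: thoracic extremes share the same column")
    midline_x0 = (kp.D2p.x + kp.D3p.x) / 2.0
    return CTRResult(dx1=dx1, dx2=dx2, ctr=dx1 / dx2, midline_x0=midline_x0)


def _stage(name: str):
    """Decorator-free stage guard: re-raise stage errors with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, LungCTRError) and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(mask: BinaryMask, config: RunConfig | None = None) -> Tuple[lm.KeypointSet, CTRResult]:
    """Run the full landmark + CTR pipeline on a binary mask.

    Deterministic: identical input and configuration give identical
    output.  Stage failures propagate as :class:`PipelineError` naming
    the failed stage and, where applicable, the failing landmark.
    """
    config = config or RunConfig()
    config.validate()

    with _stage("label_components"):
        comps = label_components(mask)
    with _stage("select_lung_fields"):
        pair = select_lung_fields(comps, min_area_frac=config.min_area_frac,
                                  rule=config.side_assignment)
    with _stage("trace_boundary"):
        cr = ct.trace_boundary(pair.right, ct.PATIENT_RIGHT)
        cl = ct.trace_boundary(pair.left, ct.PATIENT_LEFT)

    kp = lm.KeypointSet()
    with _stage("apex"):
        kp.A1 = lm.locate_apex(cr)
        kp.A2 = lm.locate_apex(cl)
    with _stage("costophrenic_angle"):
        kp.B1 = lm.locate_costophrenic_angle(cr)
        kp.B2 = lm.locate_costophrenic_angle(cl)
    with _stage("cardiophrenic_angle"):
        kp.C1 = lm.locate_cardiophrenic_angle(cr, kp.A1, kp.B1)
        kp.C2 = lm.locate_cardiophrenic_angle(cl, kp.A2, kp.B2)
    with _stage("diaphragm_top"):
        kp.D1 = lm.locate_diaphragm_top(cr, kp.B1, kp.C1)
    with _stage("thoracic_extremes"):
        kp.D2p, kp.D3p = lm.locate_thoracic_extremes(cr, cl)

    midline = lm.MidLine.at((kp.D2p.x + kp.D3p.x) / 2.0)

    with _stage("termination_point"):
        pr = ct.medial_profile(cr)
        pl = ct.medial_profile(cl)
        kp.C1p = lm.termination_point(pr, kp.C1, kp.A1,
                                      mode=config.termination_mode,
                                      f=config.cardiac_search_fraction)
        kp.C2p = lm.termination_point(pl, kp.C2, kp.A2,
                                      mode=config.termination_mode,
                                      f=config.cardiac_search_fraction)
    with _stage("heart_border"):
        kp.E1 = lm.locate_heart_border(pr, kp.C1, kp.C1p, midline)
        kp.E2 = lm.locate_heart_border(pl, kp.C2, kp.C2p, midline)
    with _stage("compute_ctr"):
        result = compute_ctr(kp)
    return kp, result


def run_batch(masks: Iterable[Tuple[str, BinaryMask]], config: RunConfig | None = None) -> List[dict]:
    """Per-frame pipeline over an ordered mask sequence.

    Returns one record per frame with the frame id, the 13 landmark
    coordinates, dx1, dx2 and ctr; a failing frame yields a record with
    an ``error`` field instead of aborting the batch.
    """
    records: List[dict] = []
    for frame_id, mask in masks:
        rec: dict = {"frame": frame_id}
        try:
            kp, res = run_pipeline(mask, config)
        except LungCTRError as exc:
            rec["error"] = str(exc)
        else:
            for name, p in kp.as_dict().items():
                rec[f"{name}_x"] = p.x
                rec[f"{name}_y"] = p.y
            rec["dx1"] = res.dx1
            rec["dx2"] = res.dx2
            rec["ctr"] = round_half_up(res.ctr, 4)
        records.append(rec)
    return records
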
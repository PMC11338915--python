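"""Lung-field post-processing: connected components, blob cleanup, sides.

A raw mask from an upstream segmenter may contain spurious blobs and
interior holes.  This module keeps exactly the two largest 8-connected
components (the lungs), fills their interior holes, and assigns patient
sides.  The default side rule uses centroid-x (patient-right lung has the
smaller image-x centroid, since patient-right appears image-left on a
postero-anterior film); the literal "largest component is the right
lung" area heuristic is available as an alternative rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy import ndimage

from .errors import ComponentError
from .mask_io import BinaryMask

logger = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class LabeledComponents:
    """8-connected foreground components of a mask; label 0 = background."""

    labels: np.ndarray
    areas: Dict[int, int]
    centroids: Dict[int, Tuple[float, float]]  # label -> (x, y)

    @property
    def n_components(self) -> int:
        return len(self.areas)


@dataclass
class LungPair:
    """The two retained lungs with patient-side assignment.

    Each side is a single 8-connected, hole-filled component; the two are
    disjoint.  Under the ``centroid`` rule, centroid-x(right) <
    centroid-x(left).
    """

    right: BinaryMask
    left: BinaryMask
    right_area: int
    left_area: int
    assignment_rule: str = "centroid"


def label_components(mask: BinaryMask) -> LabeledComponents:
    """Label the 8-connected foreground components of ``mask``."""
    if mask.foreground_count == 0:
        raise ComponentError("no foreground")
    labels, n = ndimage.label(mask.grid, structure=_STRUCT8)
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, idx)
    coms = ndimage.center_of_mass(mask.grid, labels, idx)  # (row, col)
    return LabeledComponents(
        labels=labels,
        areas={int(i): int(a) for i, a in zip(idx, areas)},
        centroids={int(i): (float(c[1]), float(c[0])) for i, c in zip(idx, coms)},
    )


def fill_holes(grid: np.ndarray) -> np.ndarray:
    """Fill interior background holes of a boolean grid (4-connected holes)."""
    return ndimage.binary_fill_holes(grid)


def select_lung_fields(
    components: LabeledComponents,
    min_area_frac: float = 0.005,
    rule: str = "centroid",
) -> LungPair:
    """Retain the two largest components as the lungs and assign sides.

    All other components are discarded (this realizes the
    connected-domain cleanup of the raw mask).  Interior holes of each
    retained component are filled.  ``rule='centroid'`` assigns
    patient-right to the component with the smaller centroid-x;
    ``rule='area_paper_literal'`` assigns patient-right to the
    larger-area component (an area tie falls back to the centroid rule
    with a warning).
    """
    if rule not in ("centroid", "area_paper_literal"):
        raise ComponentError(f"unknown side-assignment rule {rule!r}")
    h, w = components.labels.shape
    floor = min_area_frac * w * h
    qualifying = [lab for lab, a in components.areas.items() if a >= floor]
    if len(qualifying) < 2:
        raise ComponentError("merged or missing lung field")
    # two largest by area; deterministic tie-break on label id
    top2 = sorted(qualifying, key=lambda lab: (-components.areas[lab], lab))[:2]
    la, lb = top2

    masks = {lab: fill_holes(components.labels == lab) for lab in (la, lb)}
    areas = {lab: int(masks[lab].sum()) for lab in (la, lb)}
    cx = {lab: components.centroids[lab][0] for lab in (la, lb)}

    effective_rule = rule
    if rule == "area_paper_literal" and areas[la] == areas[lb]:
        logger.warning("area tie between retained components; falling back to centroid rule")
        effective_rule = "centroid"

    if effective_rule == "centroid":
        right_lab = la if cx[la] < cx[lb] else lb
    else:  # larger area is called patient-right
        right_lab = la if areas[la] > areas[lb] else lb
    left_lab = lb if right_lab == la else la

    return LungPair(
        right=BinaryMask(masks[right_lab]),
        left=BinaryMask(masks[left_lab]),
        right_area=areas[right_lab],
        left_area=areas[left_lab],
        assignment_rule=rule,
    )
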
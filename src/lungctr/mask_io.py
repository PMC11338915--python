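"""Raster mask input and result-record output.

Fixes the conventions every other module relies on:

* Coordinates are 0-based integers with the origin at the top-left pixel
  center; ``x`` indexes columns (rightward), ``y`` indexes rows
  (downward).
* On a postero-anterior radiograph the patient's right side appears on
  the image's left, so every "right"/"left" name in this package is
  PATIENT-side: the patient-right lung is the one at small ``x``.
* Binarization: a pixel is foreground iff its 8-bit (luma) intensity is
  strictly above the threshold (default 127).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import MaskInputError
from .util import round_half_up

#: serialization order of the landmark symbols
KEYPOINT_NAMES = (
    "A1", "A2", "B1", "B2", "C1", "C2", "C1p", "C2p",
    "D1", "D2p", "D3p", "E1", "E2",
)


class Point(NamedTuple):
    """Integer pixel location, ``x`` = column, ``y`` = row."""

    x: int
    y: int


@dataclass
class BinaryMask:
    """2-D foreground/background grid; foreground = lung field.

    ``grid`` is a boolean array of shape ``(height, width)`` indexed as
    ``grid[y, x]``.
    """

    grid: np.ndarray
    source_path: Optional[str] = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2 or self.grid.shape[0] < 1 or self.grid.shape[1] < 1:
            raise MaskInputError(f"mask grid must be 2-D and non-empty, got shape {self.grid.shape}")

    @property
    def height(self) -> int:
        return int(self.grid.shape[0])

    @property
    def width(self) -> int:
        return int(self.grid.shape[1])

    @property
    def foreground_count(self) -> int:
        return int(self.grid.sum())

    def __eq__(self, other) -> bool:  # grid equality; source path is metadata
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.grid.shape == other.grid.shape and bool(np.array_equal(self.grid, other.grid))


def read_mask(path, threshold: int = 127) -> BinaryMask:
    """Read a PNG/PGM/TIFF raster and binarize it.

    RGB inputs are converted to luma first.  A pixel is foreground iff
    its intensity is strictly greater than ``threshold``.
    """
    path = Path(path)
    if not (0 <= threshold <= 255):
        raise MaskInputError(f"threshold must be in [0, 255], got {threshold}")
    try:
        img = Image.open(path)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise MaskInputError(f"cannot read raster image at {path!s}: {exc}") from exc
    with img:
        if getattr(img, "n_frames", 1) > 1:
            raise MaskInputError(
                f"{path!s} is a multi-frame container; extract frames to single images first"
            )
        arr = np.asarray(img.convert("L"))
    if arr.size == 0:
        raise MaskInputError(f"zero-sized image at {path!s}")
    return BinaryMask(grid=arr > threshold, source_path=str(path))


def write_mask(mask: BinaryMask, path) -> None:
    """Write a mask as an 8-bit {0, 255} PNG/PGM/TIFF."""
    arr = np.where(mask.grid, 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def _result_record(keypoints, result) -> dict:
    rec: dict = {}
    for name in KEYPOINT_NAMES:
        p = getattr(keypoints, name)
        if p is None:
            raise MaskInputError(f"incomplete result: landmark {name} missing")
        rec[name] = [int(p.x), int(p.y)]
    rec["dx1"] = int(result.dx1)
    rec["dx2"] = int(result.dx2)
    rec["ctr"] = round_half_up(result.ctr, 4)
    rec["midline_x0"] = float(result.midline_x0)
    return rec


def write_report(keypoints, result, path, format: str = "json") -> None:
    """Write a complete landmark set + CTR record as JSON or CSV.

    Keys/columns are the landmark symbol names plus ``dx1``, ``dx2`` and
    ``ctr``; coordinates are integers and the CTR is rounded half-up to
    4 decimals.  The record round-trips through :func:`read_report`.
    """
    rec = _result_record(keypoints, result)
    path = Path(path)
    try:
        if format == "json":
            with open(path, "w") as fh:
                json.dump(rec, fh, indent=2)
                fh.write("\n")
        elif format == "csv":
            header: list[str] = []
            row: list = []
            for name in KEYPOINT_NAMES:
                header += [f"{name}_x", f"{name}_y"]
                row += rec[name]
            header += ["dx1", "dx2", "ctr", "midline_x0"]
            row += [rec["dx1"], rec["dx2"], f"{rec['ctr']:.4f}", rec["midline_x0"]]
            with open(path, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(header)
                w.writerow(row)
        else:
            raise MaskInputError(f"unknown report format {format!r}")
    except OSError as exc:
        raise MaskInputError(f"cannot write report to {path!s}: {exc}") from exc


def read_report(path, format: str = "json") -> dict:
    """Read a record written by :func:`write_report`.

    Returns a dict with :class:`Point` values for the landmark symbols
    and floats/ints for ``dx1``, ``dx2``, ``ctr``, ``midline_x0``.
    """
    path = Path(path)
    if format == "json":
        with open(path) as fh:
            raw = json.load(fh)
        out: dict = {}
        for name in KEYPOINT_NAMES:
            out[name] = Point(int(raw[name][0]), int(raw[name][1]))
        out["dx1"] = int(raw["dx1"])
        out["dx2"] = int(raw["dx2"])
        out["ctr"] = float(raw["ctr"])
        out["midline_x0"] = float(raw["midline_x0"])
        return out
    if format == "csv":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        if len(rows) != 1:
            raise MaskInputError(f"expected a single CSV record in {path!s}, got {len(rows)} rows")
        raw = rows[0]
        out = {}
        for name in KEYPOINT_NAMES:
            out[name] = Point(int(raw[f"{name}_x"]), int(raw[f"{name}_y"]))
        out["dx1"] = int(raw["dx1"])
        out["dx2"] = int(raw["dx2"])
        out["ctr"] = float(raw["ctr"])
        out["midline_x0"] = float(raw["midline_x0"])
        return out
    raise MaskInputError(f"unknown report format {format!r}")
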
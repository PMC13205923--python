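"""Attention-map weak-localization metrics against ground-truth boxes.

Four scores summarize how well an attention map agrees with annotated
nodule boxes, without detector-style IoU endpoints:

* **BBox coverage** — fraction of total attention mass falling inside
  the union of boxes.
* **Detection hit** — whether the global attention peak lies inside the
  union of boxes (dataset mean = detection rate).
* **Peak proximity** — ``1 - d/D`` with ``d`` the distance from the
  peak to the nearest box centre and ``D`` the image diagonal.
* **Attention focus** — ratio of mean attention inside the boxes to
  mean attention outside (1.0 for a uniform map).

All four are invariant to positive rescaling of the map.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .manifest import BBox, union_mask

__all__ = [
    "bbox_coverage",
    "detection_hit",
    "peak_proximity",
    "attention_focus",
    "small_nodule_filter",
    "evaluate_localization",
    "LocalizationReport",
    "SMALL_NODULE_LIMIT_PX",
]

SMALL_NODULE_LIMIT_PX = 70  # strict: a box qualifies if either side < 70


@dataclass
class LocalizationReport:
    bbox_coverage: float
    detection_rate: float
    peak_proximity: float
    attention_focus: float
    n_images: int
    per_image: pd.DataFrame | None = None


def _check(amap: np.ndarray, boxes: list[BBox]) -> np.ndarray:
    amap = np.asarray(amap, np.float64)
    if amap.ndim != 2:
        raise ValueError("attention map must be 2-D")
    if not boxes:
        raise ValueError("at least one bounding box is required")
    h, w = amap.shape
    for b in boxes:
        if not b.fits_in(h, w):
            raise ValueError(f"{b} exceeds the {h}x{w} map")
    return amap


def bbox_coverage(amap: np.ndarray, boxes: list[BBox]) -> float:
    """Attention mass inside the union of boxes over total mass."""
    amap = _check(amap, boxes)
    total = amap.sum()
    if total <= 0:
        warnings.warn("all-zero attention map: coverage defined as 0", stacklevel=2)
        return 0.0
    mask = union_mask(boxes, *amap.shape)
    return float(amap[mask].sum() / total)


def attention_peak(amap: np.ndarray) -> tuple[int, int]:
    """(row, col) of the global maximum, row-major first occurrence."""
    return tuple(int(v) for v in np.unravel_index(np.asarray(amap).argmax(), amap.shape))


def detection_hit(amap: np.ndarray, boxes: list[BBox]) -> int:
    """1 iff the attention peak lies inside the union of boxes."""
    amap = _check(amap, boxes)
    r, c = attention_peak(amap)
    return int(any(b.contains(r, c) for b in boxes))


def peak_proximity(amap: np.ndarray, boxes: list[BBox]) -> float:
    """1 - d/D: normalized distance from the peak to the nearest box centre."""
    amap = _check(amap, boxes)
    h, w = amap.shape
    r, c = attention_peak(amap)
    d = min(math.hypot(r - br, c - bc) for br, bc in (b.center for b in boxes))
    diag = math.hypot(h - 1, w - 1)
    return float(1.0 - d / diag)


def attention_focus(amap: np.ndarray, boxes: list[BBox]) -> float:
    """Mean attention inside the boxes over mean attention outside."""
    amap = _check(amap, boxes)
    mask = union_mask(boxes, *amap.shape)
    if mask.all():
        raise ValueError("boxes cover the whole map: outside region is empty")
    outside = amap[~mask].mean()
    inside = amap[mask].mean()
    if outside <= 0:
        return math.inf  # sentinel: all mass concentrated inside the boxes
    return float(inside / outside)


def small_nodule_filter(df: pd.DataFrame) -> pd.DataFrame:
    """Positive rows with at least one box strictly below the small-nodule
    limit in width or height (70 px in either dimension)."""
    pos = df[df["label"] == 1]
    empty = pos[pos["boxes"].map(len) == 0]
    if len(empty):
        raise ValueError(f"{len(empty)} positive rows carry no bounding boxes")
    keep = pos["boxes"].map(
        lambda boxes: any(b.width < SMALL_NODULE_LIMIT_PX or b.height < SMALL_NODULE_LIMIT_PX for b in boxes)
    )
    return pos[keep]


def evaluate_localization(maps: dict[str, np.ndarray], df: pd.DataFrame) -> LocalizationReport:
    """Score attention maps for every positive row of ``df``.

    ``maps`` keys are image paths (manifest ``image_path`` values).
    """
    rows = []
    for row in df[df["label"] == 1].itertuples():
        amap = maps[row.image_path]
        rows.append(
            {
                "image_path": row.image_path,
                "bbox_coverage": bbox_coverage(amap, row.boxes),
                "detection_hit": detection_hit(amap, row.boxes),
                "peak_proximity": peak_proximity(amap, row.boxes),
                "attention_focus": attention_focus(amap, row.boxes),
            }
        )
    if not rows:
        raise ValueError("no positive rows to evaluate")
    per_image = pd.DataFrame(rows)
    finite_focus = per_image["attention_focus"].replace(math.inf, np.nan)
    return LocalizationReport(
        bbox_coverage=float(per_image["bbox_coverage"].mean()),
        detection_rate=float(per_image["detection_hit"].mean()),
        peak_proximity=float(per_image["peak_proximity"].mean()),
        attention_focus=float(finite_focus.mean()),
        n_images=len(per_image),
        per_image=per_image,
    )
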
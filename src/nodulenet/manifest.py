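"""Dataset manifest schema and CSV round-tripping.

A manifest row describes one radiograph: ``patient_id``, ``image_path``,
binary ``label`` (1 = nodule present), ``split`` assignment, and zero or
more pixel bounding boxes serialized as semicolon-joined ``x,y,w,h``
quadruples (0-based, half-open, NODE21 CSV style).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MANIFEST_COLUMNS = ["patient_id", "image_path", "label", "split", "boxes"]


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box covering [x_min, x_min+width) x [y_min, y_min+height)."""

    x_min: int
    y_min: int
    width: int
    height: int

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"box dimensions must be positive: {self}")
        if self.x_min < 0 or self.y_min < 0:
            raise ValueError(f"box origin must be non-negative: {self}")

    @property
    def x_max(self) -> int:  # exclusive
        return self.x_min + self.width

    @property
    def y_max(self) -> int:  # exclusive
        return self.y_min + self.height

    @property
    def center(self) -> tuple[float, float]:
        """(row, col) of the box centre in pixel-centre coordinates."""
        return (self.y_min + (self.height - 1) / 2.0, self.x_min + (self.width - 1) / 2.0)

    def contains(self, row: int, col: int) -> bool:
        return self.y_min <= row < self.y_max and self.x_min <= col < self.x_max

    def fits_in(self, height: int, width: int) -> bool:
        return self.x_max <= width and self.y_max <= height


def boxes_to_str(boxes: list[BBox]) -> str:
    return ";".join(f"{b.x_min},{b.y_min},{b.width},{b.height}" for b in boxes)


def boxes_from_str(s: str) -> list[BBox]:
    if not isinstance(s, str) or not s.strip():
        return []
    out = []
    for part in s.split(";"):
        x, y, w, h = (int(v) for v in part.split(","))
        out.append(BBox(x, y, w, h))
    return out


def union_mask(boxes: list[BBox], height: int, width: int) -> np.ndarray:
    """Boolean raster of the union of boxes on a height x width grid."""
    m = np.zeros((height, width), bool)
    for b in boxes:
        m[b.y_min : b.y_max, b.x_min : b.x_max] = True
    return m


def write_manifest(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if len(out) and not isinstance(out["boxes"].iloc[0], str):
        out["boxes"] = out["boxes"].map(boxes_to_str)
    out[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "image_path": str, "split": str}, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    df["label"] = df["label"].astype(int)
    df["boxes"] = df["boxes"].map(boxes_from_str)
    bad = df[(df["label"] == 1) != (df["boxes"].map(len) > 0)]
    if len(bad):
        raise ValueError(f"label/box inconsistency for {len(bad)} manifest rows")
    return df
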
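"""Bounding-box representations and IoU/GIoU geometry.

Two coordinate conventions coexist and are converted explicitly:

* :class:`Box` — normalized center form ``(cx, cy, w, h)`` with every field
  in ``[0, 1]``; this is what the detector predicts and what losses consume.
* :class:`PixelBox` — corner form in 0-based pixel coordinates, origin at the
  top-left, x rightward and y downward, half-open on the max edges (so a box
  covering the full 100x100 frame is ``(0, 0, 100, 100)``).

GIoU extends IoU with a penalty for the empty part of the smallest enclosing
axis-aligned box, so fully disjoint boxes still produce a useful (negative)
value instead of a flat zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Box", "PixelBox", "box_to_pixels", "box_from_pixels",
    "iou", "giou", "iou_matrix", "giou_matrix",
    "cxcywh_to_xyxy", "xyxy_to_cxcywh",
]


@dataclass(frozen=True)
class Box:
    """Normalized center-form bounding box."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise ValueError(f"box center ({self.cx}, {self.cy}) outside [0, 1]")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise ValueError(f"box size ({self.w}, {self.h}) outside (0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.cx, self.cy, self.w, self.h])


@dataclass(frozen=True)
class PixelBox:
    """Corner-form box in pixels, half-open on the max edges."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("degenerate pixel box: min edges must precede max edges")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


def box_to_pixels(box: Box, width: float, height: float) -> PixelBox:
    """Map a normalized box onto a ``width x height`` pixel frame.

    No clamping is applied: a box that extends past the frame keeps its
    out-of-bounds corners (callers clamp where their format requires it).
    """
    if width <= 0 or height <= 0:
        raise ValueError("image dimensions must be positive")
    return PixelBox(
        x_min=(box.cx - box.w / 2.0) * width,
        y_min=(box.cy - box.h / 2.0) * height,
        x_max=(box.cx + box.w / 2.0) * width,
        y_max=(box.cy + box.h / 2.0) * height,
    )


def box_from_pixels(pb: PixelBox, width: float, height: float) -> Box:
    if width <= 0 or height <= 0:
        raise ValueError("image dimensions must be positive")
    return Box(
        cx=(pb.x_min + pb.x_max) / 2.0 / width,
        cy=(pb.y_min + pb.y_max) / 2.0 / height,
        w=(pb.x_max - pb.x_min) / width,
        h=(pb.y_max - pb.y_min) / height,
    )


def iou(a: PixelBox, b: PixelBox) -> float:
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def giou(a: PixelBox, b: PixelBox) -> float:
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    enclosure = ((max(a.x_max, b.x_max) - min(a.x_min, b.x_min))
                 * (max(a.y_max, b.y_max) - min(a.y_min, b.y_min)))
    return inter / union - (enclosure - union) / enclosure


# -- vectorized forms used by matching and evaluation -------------------------


def cxcywh_to_xyxy(boxes: np.ndarray) -> np.ndarray:
    """(N, 4) center-form -> corner-form, same units."""
    boxes = np.asarray(boxes, dtype=np.float64)
    half = boxes[..., 2:] / 2.0
    return np.concatenate([boxes[..., :2] - half, boxes[..., :2] + half], axis=-1)


def xyxy_to_cxcywh(boxes: np.ndarray) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=np.float64)
    wh = boxes[..., 2:] - boxes[..., :2]
    return np.concatenate([boxes[..., :2] + wh / 2.0, wh], axis=-1)


def _pairwise_inter_union(a_xyxy: np.ndarray, b_xyxy: np.ndarray):
    lt = np.maximum(a_xyxy[:, None, :2], b_xyxy[None, :, :2])
    rb = np.minimum(a_xyxy[:, None, 2:], b_xyxy[None, :, 2:])
    wh = np.clip(rb - lt, 0.0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a_xyxy[:, 2] - a_xyxy[:, 0]) * (a_xyxy[:, 3] - a_xyxy[:, 1])
    area_b = (b_xyxy[:, 2] - b_xyxy[:, 0]) * (b_xyxy[:, 3] - b_xyxy[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return inter, union


def iou_matrix(a_xyxy: np.ndarray, b_xyxy: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (N, 4) and (M, 4) corner-form boxes."""
    inter, union = _pairwise_inter_union(np.asarray(a_xyxy, dtype=np.float64),
                                         np.asarray(b_xyxy, dtype=np.float64))
    return inter / union


def giou_matrix(a_xyxy: np.ndarray, b_xyxy: np.ndarray) -> np.ndarray:
    """Pairwise GIoU between (N, 4) and (M, 4) corner-form boxes."""
    a = np.asarray(a_xyxy, dtype=np.float64)
    b = np.asarray(b_xyxy, dtype=np.float64)
    inter, union = _pairwise_inter_union(a, b)
    lt = np.minimum(a[:, None, :2], b[None, :, :2])
    rb = np.maximum(a[:, None, 2:], b[None, :, 2:])
    wh = rb - lt
    enclosure = wh[..., 0] * wh[..., 1]
    return inter / union - (enclosure - union) / enclosure
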
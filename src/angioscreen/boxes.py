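"""Axis-aligned box arithmetic.

Boxes are 0-based half-open pixel intervals ``(x_min, y_min, x_max, y_max)``:
the pixel column ``x_max`` is *not* inside the box, so a box's area is simply
``(x_max - x_min) * (y_max - y_min)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["box_area", "iou", "clip_box", "box_center", "nms"]


def box_area(box) -> float:
    x0, y0, x1, y1 = box
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"zero-area or inverted box {box}")
    return float((x1 - x0) * (y1 - y0))


def iou(box_a, box_b) -> float:
    """Intersection over union by area, in [0, 1]."""
    area_a, area_b = box_area(box_a), box_area(box_b)
    ix0 = max(box_a[0], box_b[0])
    iy0 = max(box_a[1], box_b[1])
    ix1 = min(box_a[2], box_b[2])
    iy1 = min(box_a[3], box_b[3])
    inter = max(ix1 - ix0, 0.0) * max(iy1 - iy0, 0.0)
    return float(inter / (area_a + area_b - inter))


def clip_box(box, width: int, height: int):
    x0, y0, x1, y1 = box
    return (max(x0, 0), max(y0, 0), min(x1, width), min(y1, height))


def box_center(box):
    x0, y0, x1, y1 = box
    return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


def nms(boxes, scores, iou_threshold: float = 0.5):
    """Greedy non-maximum suppression; returns indices kept, by score order."""
    order = np.argsort(scores)[::-1]
    keep = []
    while len(order):
        i = order[0]
        keep.append(int(i))
        rest = order[1:]
        order = np.array([j for j in rest
                          if iou(boxes[i], boxes[j]) <= iou_threshold], dtype=int)
    return keep
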
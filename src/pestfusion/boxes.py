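"""Bounding-box conversions and overlap geometry.

Boxes are normalized (cx, cy, w, h) inside the model (sigmoid outputs)
and corner-pixel (x_min, y_min, x_max, y_max) at I/O boundaries; all
conversions live here.  ``iou`` and ``giou`` have twin implementations:
plain numpy for matching/evaluation and an autodiff version used inside
the loss.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["cxcywh_to_xyxy", "xyxy_to_cxcywh", "iou_xyxy", "giou_xyxy",
           "giou_tensor", "tensor_max", "tensor_min"]


def cxcywh_to_xyxy(boxes: np.ndarray) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=float)
    cx, cy, w, h = boxes[..., 0], boxes[..., 1], boxes[..., 2], boxes[..., 3]
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=-1)


def xyxy_to_cxcywh(boxes: np.ndarray) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=float)
    x0, y0, x1, y1 = boxes[..., 0], boxes[..., 1], boxes[..., 2], boxes[..., 3]
    return np.stack([(x0 + x1) / 2, (y0 + y1) / 2, x1 - x0, y1 - y0], axis=-1)


def _validate_xyxy(boxes: np.ndarray) -> None:
    if (boxes[..., 2] <= boxes[..., 0]).any() or (boxes[..., 3] <= boxes[..., 1]).any():
        raise ValueError("degenerate box: requires x_max > x_min and y_max > y_min")


def iou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of broadcast-compatible xyxy boxes, in [0,1]."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    _validate_xyxy(a)
    _validate_xyxy(b)
    ix = np.clip(np.minimum(a[..., 2], b[..., 2]) - np.maximum(a[..., 0], b[..., 0]), 0, None)
    iy = np.clip(np.minimum(a[..., 3], b[..., 3]) - np.maximum(a[..., 1], b[..., 1]), 0, None)
    inter = ix * iy
    area_a = (a[..., 2] - a[..., 0]) * (a[..., 3] - a[..., 1])
    area_b = (b[..., 2] - b[..., 0]) * (b[..., 3] - b[..., 1])
    union = area_a + area_b - inter
    return inter / union


def giou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Generalized IoU: IoU - (hull - union)/hull, in [-1, 1]."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    _validate_xyxy(a)
    _validate_xyxy(b)
    ix = np.clip(np.minimum(a[..., 2], b[..., 2]) - np.maximum(a[..., 0], b[..., 0]), 0, None)
    iy = np.clip(np.minimum(a[..., 3], b[..., 3]) - np.maximum(a[..., 1], b[..., 1]), 0, None)
    inter = ix * iy
    area_a = (a[..., 2] - a[..., 0]) * (a[..., 3] - a[..., 1])
    area_b = (b[..., 2] - b[..., 0]) * (b[..., 3] - b[..., 1])
    union = area_a + area_b - inter
    hull = (np.maximum(a[..., 2], b[..., 2]) - np.minimum(a[..., 0], b[..., 0])) * \
           (np.maximum(a[..., 3], b[..., 3]) - np.minimum(a[..., 1], b[..., 1]))
    return inter / union - (hull - union) / hull


def tensor_max(a: Tensor, b: Tensor) -> Tensor:
    mask = Tensor((a.data >= b.data).astype(float))
    return a * mask + b * (1.0 - mask)


def tensor_min(a: Tensor, b: Tensor) -> Tensor:
    mask = Tensor((a.data <= b.data).astype(float))
    return a * mask + b * (1.0 - mask)


def giou_tensor(pred_cxcywh: Tensor, gt_xyxy: np.ndarray) -> Tensor:
    """Differentiable GIoU between predicted (M,4) cxcywh boxes and fixed gts."""
    cx, cy = pred_cxcywh[:, 0], pred_cxcywh[:, 1]
    w, h = pred_cxcywh[:, 2], pred_cxcywh[:, 3]
    half = 0.5
    px0, py0 = cx - w * half, cy - h * half
    px1, py1 = cx + w * half, cy + h * half
    g = np.asarray(gt_xyxy, dtype=float)
    gx0, gy0, gx1, gy1 = (Tensor(g[:, i]) for i in range(4))
    zero = Tensor(np.zeros(g.shape[0]))
    ix = tensor_max(tensor_min(px1, gx1) - tensor_max(px0, gx0), zero)
    iy = tensor_max(tensor_min(py1, gy1) - tensor_max(py0, gy0), zero)
    inter = ix * iy
    area_p = (px1 - px0) * (py1 - py0)
    area_g = (gx1 - gx0) * (gy1 - gy0)
    union = area_p + area_g - inter
    hull = (tensor_max(px1, gx1) - tensor_min(px0, gx0)) * \
           (tensor_max(py1, gy1) - tensor_min(py0, gy0))
    return inter / union - (hull - union) / hull
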
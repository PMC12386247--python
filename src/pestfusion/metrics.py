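"""Detection metrics: precision, recall, F1, per-class AP and mAP@50.

The matching protocol is the PASCAL-VOC convention the formulas leave
implicit: within each (image, class) pair, detections are visited in
descending score order and greedily matched one-to-one to the
highest-IoU unmatched ground-truth box; a detection is a true positive
iff that IoU is >= the threshold (0.5 here).  Average precision uses
all-point interpolation (the precision envelope is made monotone
non-increasing before integrating the PR curve); an 11-point variant is
available for comparison.  mAP@50 is the unweighted mean of per-class
AP over classes with at least one ground-truth instance; a group map
can collapse the 8 fine classes onto the pest/predator super-classes
before evaluation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .boxes import iou_xyxy

__all__ = ["DetectionRecord", "GroundTruthRecord", "MetricsReport", "iou",
           "match_detections", "precision_recall_f1", "average_precision",
           "map50", "evaluate_detections", "GROUP_MAP", "format_report_table"]

GROUP_MAP = {i: 0 for i in range(6)} | {6: 1, 7: 1}   # fine -> {pest, predator}


@dataclass(frozen=True)
class DetectionRecord:
    image_id: int
    label: int
    score: float
    box: tuple[float, float, float, float]   # xyxy pixels

    def __post_init__(self):
        if not np.isfinite(self.score):
            raise ValueError("non-finite score")


@dataclass(frozen=True)
class GroundTruthRecord:
    image_id: int
    label: int
    box: tuple[float, float, float, float]


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    ap_per_class: dict[int, float]
    map50: float
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "precision": self.precision, "recall": self.recall,
                "f1": self.f1,
                "ap_per_class": {str(k): v for k, v in self.ap_per_class.items()},
                "map50": self.map50, **self.extras}


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two xyxy boxes."""
    return float(iou_xyxy(np.asarray(box_a), np.asarray(box_b)))


def match_detections(dets: list[DetectionRecord], gts: list[GroundTruthRecord],
                     iou_threshold: float = 0.5
                     ) -> tuple[int, int, int, list[bool]]:
    """Greedy score-ordered one-to-one matching within (image, class).

    Returns (TP, FP, FN, per-detection TP flags in the original order of
    ``dets``).
    """
    gt_index: dict[tuple[int, int], list[GroundTruthRecord]] = defaultdict(list)
    for gt in gts:
        gt_index[(gt.image_id, gt.label)].append(gt)
    matched: dict[tuple[int, int], np.ndarray] = {
        key: np.zeros(len(v), dtype=bool) for key, v in gt_index.items()}

    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    flags = [False] * len(dets)
    for i in order:
        det = dets[i]
        key = (det.image_id, det.label)
        candidates = gt_index.get(key, [])
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(candidates):
            if matched[key][j]:
                continue
            overlap = iou(det.box, gt.box)
            if overlap > best_iou:
                best_iou, best_j = overlap, j
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[key][best_j] = True
            flags[i] = True
    tp = sum(flags)
    fp = len(dets) - tp
    fn = len(gts) - tp
    return tp, fp, fn, flags


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); 0 on empty denominators."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


def average_precision(tp_flags: list[bool], scores: list[float], n_gt: int,
                      eleven_point: bool = False) -> float:
    """Area under the PR curve for one class.

    ``tp_flags``/``scores`` are per-detection; detections are ranked by
    descending score.  All-point interpolation by default.
    """
    if n_gt < 1:
        raise ValueError("average_precision requires >= 1 ground-truth instance")
    if not tp_flags:
        return 0.0
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    flags = np.asarray(tp_flags, dtype=bool)[order]
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    if eleven_point:
        return float(np.mean([
            precision[recall >= r].max() if (recall >= r).any() else 0.0
            for r in np.linspace(0, 1, 11)]))
    # precision envelope: monotone non-increasing in recall
    mrec = np.concatenate([[0.0], recall, [1.0]])
    mpre = np.concatenate([[0.0], precision, [0.0]])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    changes = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[changes + 1] - mrec[changes]) * mpre[changes + 1]))


def map50(ap_per_class: dict[int, float]) -> float:
    """Unweighted mean of per-class AP over evaluable classes."""
    if not ap_per_class:
        raise ValueError("no evaluable classes")
    return float(np.mean(list(ap_per_class.values())))


def evaluate_detections(dets: list[DetectionRecord], gts: list[GroundTruthRecord],
                        iou_threshold: float = 0.5,
                        group_map: dict[int, int] | None = None,
                        eleven_point: bool = False) -> MetricsReport:
    """Full evaluation pass; ``group_map`` collapses labels beforehand."""
    if group_map is not None:
        dets = [DetectionRecord(d.image_id, group_map[d.label], d.score, d.box)
                for d in dets]
        gts = [GroundTruthRecord(g.image_id, group_map[g.label], g.box)
               for g in gts]
    tp, fp, fn, flags = match_detections(dets, gts, iou_threshold)
    p, r, f1 = precision_recall_f1(tp, fp, fn)
    ap: dict[int, float] = {}
    gt_classes = sorted({g.label for g in gts})
    for cls in gt_classes:
        cls_idx = [i for i, d in enumerate(dets) if d.label == cls]
        n_gt = sum(1 for g in gts if g.label == cls)
        ap[cls] = average_precision([flags[i] for i in cls_idx],
                                    [dets[i].score for i in cls_idx],
                                    n_gt, eleven_point)
    return MetricsReport(tp=tp, fp=fp, fn=fn, precision=p, recall=r, f1=f1,
                         ap_per_class=ap, map50=map50(ap) if ap else 0.0)


def format_report_table(rows: dict[str, MetricsReport]) -> str:
    """Plain-text table: Precision/Recall/F1/mAP@50 as percentages, 1 decimal."""
    header = f"{'Model':<24}{'Precision (%)':>14}{'Recall (%)':>12}" \
             f"{'F1-Score (%)':>14}{'mAP@50 (%)':>12}"
    lines = [header, "-" * len(header)]
    for name, rep in rows.items():
        lines.append(f"{name:<24}{100 * rep.precision:>14.1f}"
                     f"{100 * rep.recall:>12.1f}{100 * rep.f1:>14.1f}"
                     f"{100 * rep.map50:>12.1f}")
    return "\n".join(lines)
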
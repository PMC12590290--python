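"""Precision / recall / F1 evaluation of picked coordinates.

A pick matches an unclaimed ground-truth particle when their center distance
is at most a per-particle radius (default: half the truth box's mean side —
natural for the near-square boxes of roughly round particles). An IoU >= 0.5
criterion is available for comparability with the detection literature; it
needs predicted boxes, not just centers. Matching is greedy in descending
score order, the standard detection-evaluation convention; among equal
scores the earlier pick wins.

Counts are pooled over micrographs within a dataset (micro-averaging);
across datasets the arithmetic mean of per-dataset metrics is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import PixelBox, box_to_pixels, iou
from .io_formats import AnnotationSet, PickedParticle

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchCriterion:
    mode: str = "center"        # "center" or "iou"
    radius_factor: float = 0.5  # fraction of the truth box mean side (center mode)
    iou_threshold: float = 0.5  # (iou mode)

    def __post_init__(self):
        if self.mode not in {"center", "iou"}:
            raise ValueError("mode must be 'center' or 'iou'")

    def describe(self) -> str:
        if self.mode == "center":
            return f"center distance <= {self.radius_factor} x truth mean side"
        return f"IoU >= {self.iou_threshold}"


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    criterion: str = ""


def compute_prf(tp: int, fp: int, fn: int,
                criterion: str = "") -> EvalReport:
    """P = tp/(tp+fp), R = tp/(tp+fn), F1 = 2PR/(P+R); 0 on empty denominators."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalReport(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall,
                      f1=f1, criterion=criterion)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    return 2 * precision * recall / (precision + recall) if precision + recall else 0.0


def match_picks(preds: list[PickedParticle], truth: AnnotationSet,
                criterion: MatchCriterion = MatchCriterion(),
                pred_boxes: list[PixelBox] | None = None
                ) -> tuple[int, int, int]:
    """Greedy one-to-one matching of picks to truth; returns (tp, fp, fn)."""
    if criterion.mode == "iou" and pred_boxes is None:
        raise ValueError("IoU matching requires predicted boxes")
    for p in preds:
        if p.micrograph_name not in truth.images:
            raise ValueError(f"pick references unknown micrograph {p.micrograph_name!r}")
    tp = fp = 0
    n_truth = len(truth.records)
    claimed = np.zeros(n_truth, dtype=bool)
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].score, i))
    truth_px = []
    for r in truth.records:
        info = truth.images[r.micrograph_id]
        pb = box_to_pixels(r.box, info.width, info.height)
        truth_px.append((r.micrograph_id, pb))
    for i in order:
        p = preds[i]
        best_j = -1
        best_key = None
        for j, (mid, pb) in enumerate(truth_px):
            if claimed[j] or mid != p.micrograph_name:
                continue
            if criterion.mode == "center":
                mean_side = ((pb.x_max - pb.x_min) + (pb.y_max - pb.y_min)) / 2.0
                radius = criterion.radius_factor * mean_side
                d = np.hypot(p.x - (pb.x_min + pb.x_max) / 2.0,
                             p.y - (pb.y_min + pb.y_max) / 2.0)
                if d <= radius and (best_key is None or d < best_key):
                    best_j, best_key = j, d
            else:
                overlap = iou(pred_boxes[i], pb)
                if overlap >= criterion.iou_threshold and (
                        best_key is None or -overlap < best_key):
                    best_j, best_key = j, -overlap
        if best_j >= 0:
            claimed[best_j] = True
            tp += 1
        else:
            fp += 1
    fn = int(n_truth - claimed.sum())
    return tp, fp, fn


def evaluate_dataset(preds: list[PickedParticle], truth: AnnotationSet,
                     criterion: MatchCriterion = MatchCriterion()
                     ) -> tuple[EvalReport, list[dict]]:
    """Micro-averaged report over a dataset plus a per-micrograph table.

    Truth micrographs with no picks at all contribute their particles as
    false negatives (logged).
    """
    by_mic: dict[str, list[PickedParticle]] = {name: [] for name in truth.images}
    for p in preds:
        if p.micrograph_name not in by_mic:
            raise ValueError(f"pick references unknown micrograph {p.micrograph_name!r}")
        by_mic[p.micrograph_name].append(p)
    rows = []
    tp = fp = fn = 0
    for name in truth.images:
        sub_truth = AnnotationSet(
            images={name: truth.images[name]},
            records=[r for r in truth.records if r.micrograph_id == name])
        if not by_mic[name] and sub_truth.records:
            logger.info("no picks on %s: %d particles counted as FN",
                        name, len(sub_truth.records))
        t, f_, n = match_picks(by_mic[name], sub_truth, criterion)
        rows.append({"micrograph": name, "tp": t, "fp": f_, "fn": n})
        tp, fp, fn = tp + t, fp + f_, fn + n
    return compute_prf(tp, fp, fn, criterion.describe()), rows


def average_reports(reports: list[EvalReport]) -> EvalReport:
    """Arithmetic mean of per-dataset metrics (the multi-dataset convention)."""
    if not reports:
        raise ValueError("no reports to average")
    return EvalReport(
        tp=sum(r.tp for r in reports), fp=sum(r.fp for r in reports),
        fn=sum(r.fn for r in reports),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        criterion=reports[0].criterion if reports else "")
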
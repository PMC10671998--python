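"""Single-class detection evaluation.

The protocol scores one class ("lesion") only: every matched prediction with
IOU above 0.5 is a true positive, everything else a false positive, and true
negatives and false negatives are fixed at zero.  Two identities follow
directly and are part of the contract:

* sensitivity = TP / (TP + FN) = 1 whenever anything was detected, and
* accuracy = TP / (TP + FP + TN + FN) = TP / (TP + FP) = precision.

Ground-truth boxes are matched to predictions greedily in descending IOU
order; ground-truth boxes left unmatched enter the tally as IOU-0 pairs (and
hence false positives), keeping the TN = FN = 0 accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import BoundingBox, BoxArray
from .losses import iou

__all__ = ["DetectionReport", "match_boxes", "confusion_counts", "summarize"]

IOU_THRESHOLD = 0.5


@dataclass
class DetectionReport:
    tp: int
    fp: int
    accuracy: float
    precision: float
    sensitivity: float
    f1: float
    mean_iou: float
    per_image: list = field(default_factory=list)  # matched IOUs
    no_detections: bool = False
    tn: int = 0
    fn: int = 0

    def to_text(self) -> str:
        pairs = [("tp", self.tp), ("fp", self.fp), ("tn", self.tn),
                 ("fn", self.fn), ("accuracy", self.accuracy),
                 ("precision", self.precision),
                 ("sensitivity", self.sensitivity), ("f1", self.f1),
                 ("mean_iou", self.mean_iou)]
        return "\n".join(f"{k} = {v}" for k, v in pairs) + "\n"

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.write_text(self.to_text())
        pd.DataFrame({"iou": self.per_image}).to_csv(
            path.with_suffix(".ious.csv"), index=False)


def match_boxes(pred: BoxArray, actual: BoxArray) -> list[tuple[int, int, float]]:
    """Greedy one-to-one assignment in descending IOU order.

    Returns (actual_index, pred_index, iou) triples; unmatched ground-truth
    boxes appear with pred_index -1 and IOU 0.  Sentinel slots on either side
    are ignored.
    """
    act_idx = [i for i, s in enumerate(actual.sentinel_mask) if not s]
    pred_idx = [j for j, s in enumerate(pred.sentinel_mask) if not s]
    pairs = []
    for i in act_idx:
        for j in pred_idx:
            pairs.append((iou(BoundingBox(*actual.boxes[i]),
                              BoundingBox(*pred.boxes[j])), i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_p: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for value, i, j in pairs:
        if i in used_a or j in used_p:
            continue
        used_a.add(i)
        used_p.add(j)
        matches.append((i, j, value))
    for i in act_idx:
        if i not in used_a:
            matches.append((i, -1, 0.0))
    matches.sort(key=lambda t: t[0])
    return matches


def confusion_counts(matched_ious: list[float],
                     threshold: float = IOU_THRESHOLD) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) with tn = fn = 0; IOU strictly above threshold is TP."""
    ious = np.asarray(matched_ious, dtype=float)
    if ious.size and (ious.min() < 0.0 or ious.max() > 1.0):
        raise ValueError("IOU values must lie in [0, 1]")
    tp = int((ious > threshold).sum())
    fp = int(ious.size - tp)
    return tp, fp, 0, 0


def summarize(tp: int, fp: int, matched_ious: list[float]) -> DetectionReport:
    """Aggregate counts into the single-class report.

    With TN = FN = 0: accuracy == precision == tp/(tp+fp); sensitivity is 1
    by construction whenever there is at least one detection.  An empty
    evaluation (tp + fp = 0) reports zeros with the no_detections flag set.
    """
    if tp + fp == 0:
        return DetectionReport(tp=0, fp=0, accuracy=0.0, precision=0.0,
                               sensitivity=0.0, f1=0.0, mean_iou=0.0,
                               per_image=list(matched_ious), no_detections=True)
    precision = tp / (tp + fp)
    accuracy = tp / (tp + fp + 0 + 0)
    sensitivity = 1.0
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if precision + sensitivity > 0 else 0.0)
    mean_iou = float(np.mean(matched_ious)) if len(matched_ious) else 0.0
    return DetectionReport(tp=tp, fp=fp, accuracy=accuracy, precision=precision,
                           sensitivity=sensitivity, f1=f1, mean_iou=mean_iou,
                           per_image=list(matched_ious))
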
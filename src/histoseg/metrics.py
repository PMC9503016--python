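"""Segmentation evaluation: IoU, DICE, F1 and frequency-weighted IoU.

Per class c with binary layers P (prediction) and T (truth):

    IoU_c  = |P and T| / |P or T|
    DICE_c = 2 |P and T| / (|P| + |T|)   ( = 2 IoU / (1 + IoU) )
    F1_c   = 2 precision recall / (precision + recall)   ( = DICE_c )
    F_W    = sum_c freq_c(T) * IoU_c

A class empty in both masks scores 1.0 in every metric (consistent
empty-class convention).  Across-slide summaries report mean and standard
deviation per metric; the population convention (ddof=0) is the default
and switchable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import LabelMask
from .synthetic import CLASS_NAMES

__all__ = ["EvalReport", "iou", "dice", "f1", "frequency_weighted_iou",
           "evaluate_mask", "summarize"]

NUM_CLASSES = 3


def _layers(pred, truth, cls: int) -> tuple[np.ndarray, np.ndarray]:
    pred = pred.labels if isinstance(pred, LabelMask) else np.asarray(pred)
    truth = truth.labels if isinstance(truth, LabelMask) else np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    return pred == cls, truth == cls


def iou(pred, truth, cls: int) -> float:
    p, t = _layers(pred, truth, cls)
    union = np.count_nonzero(p | t)
    if union == 0:
        return 1.0
    return np.count_nonzero(p & t) / union


def dice(pred, truth, cls: int) -> float:
    p, t = _layers(pred, truth, cls)
    total = np.count_nonzero(p) + np.count_nonzero(t)
    if total == 0:
        return 1.0
    return 2.0 * np.count_nonzero(p & t) / total


def f1(pred, truth, cls: int) -> float:
    p, t = _layers(pred, truth, cls)
    tp = np.count_nonzero(p & t)
    fp = np.count_nonzero(p & ~t)
    fn = np.count_nonzero(~p & t)
    if tp + fp + fn == 0:
        return 1.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def frequency_weighted_iou(pred, truth) -> float:
    truth_arr = (truth.labels if isinstance(truth, LabelMask)
                 else np.asarray(truth))
    total = truth_arr.size
    out = 0.0
    for cls in range(NUM_CLASSES):
        freq = np.count_nonzero(truth_arr == cls) / total
        if freq > 0:
            out += freq * iou(pred, truth, cls)
    return out


@dataclass
class EvalReport:
    per_class_iou: dict = field(default_factory=dict)
    per_class_dice: dict = field(default_factory=dict)
    per_class_f1: dict = field(default_factory=dict)
    mean_iou: float = 0.0
    fw_iou: float = 0.0

    def as_rows(self) -> list[tuple]:
        rows = []
        for c, name in enumerate(CLASS_NAMES):
            rows.append((name, self.per_class_iou[name],
                         self.per_class_dice[name], self.per_class_f1[name]))
        rows.append(("mean", self.mean_iou, None, None))
        rows.append(("F_W", self.fw_iou, None, None))
        return rows

    def to_csv(self) -> str:
        lines = ["class,iou,dice,f1"]
        for name in CLASS_NAMES:
            lines.append(f"{name},{self.per_class_iou[name]:.6f},"
                         f"{self.per_class_dice[name]:.6f},"
                         f"{self.per_class_f1[name]:.6f}")
        lines.append(f"mean,{self.mean_iou:.6f},,")
        lines.append(f"F_W,{self.fw_iou:.6f},,")
        return "\n".join(lines) + "\n"


def _align(pred, truth):
    """Upsample the prediction to the truth resolution (nearest) if needed."""
    p = pred.labels if isinstance(pred, LabelMask) else np.asarray(pred)
    t = truth.labels if isinstance(truth, LabelMask) else np.asarray(truth)
    if p.shape != t.shape:
        fy = t.shape[0] / p.shape[0]
        fx = t.shape[1] / p.shape[1]
        yy = np.minimum((np.arange(t.shape[0]) / fy).astype(int),
                        p.shape[0] - 1)
        xx = np.minimum((np.arange(t.shape[1]) / fx).astype(int),
                        p.shape[1] - 1)
        p = p[np.ix_(yy, xx)]
    return p, t


def evaluate_mask(pred, truth) -> EvalReport:
    p, t = _align(pred, truth)
    report = EvalReport()
    ious = []
    for c, name in enumerate(CLASS_NAMES):
        report.per_class_iou[name] = iou(p, t, c)
        report.per_class_dice[name] = dice(p, t, c)
        report.per_class_f1[name] = f1(p, t, c)
        ious.append(report.per_class_iou[name])
    report.mean_iou = float(np.mean(ious))
    report.fw_iou = frequency_weighted_iou(p, t)
    return report


def summarize(reports: list[EvalReport], ddof: int = 0) -> dict:
    """Across-slide mean +/- STD per metric (population STD by default)."""
    if not reports:
        raise ValueError("no reports to summarize")
    out: dict[str, tuple] = {}
    for name in CLASS_NAMES:
        for metric, attr in (("iou", "per_class_iou"),
                             ("dice", "per_class_dice"),
                             ("f1", "per_class_f1")):
            vals = np.array([getattr(r, attr)[name] for r in reports])
            out[f"{metric}_{name}"] = (float(vals.mean()),
                                       float(vals.std(ddof=ddof)))
    for metric in ("mean_iou", "fw_iou"):
        vals = np.array([getattr(r, metric) for r in reports])
        out[metric] = (float(vals.mean()), float(vals.std(ddof=ddof)))
    return out
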
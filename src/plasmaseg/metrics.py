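"""Instance matching and detection metrics (TPR, PPV, F1, FDR).

A predicted cell counts as a true positive only when it matches a
ground-truth cell essentially completely; partial or over-segmented cells
are discarded.  "Complete" is operationalized as an intersection-over-union
of at least ``iou_complete`` under greedy one-to-one matching.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class DetectionCounts:
    """True/false positive and false negative instance counts."""

    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    def __add__(self, other: "DetectionCounts") -> "DetectionCounts":
        return DetectionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricReport:
    """Detection metrics as percentages (two decimals); None if undefined."""

    tpr: float | None
    ppv: float | None
    f1: float | None
    fdr: float | None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    def to_csv_row(self, method: str) -> str:
        fmt = lambda v: "" if v is None else f"{v:.2f}"
        return f"{method},{fmt(self.tpr)},{fmt(self.ppv)},{fmt(self.fdr)},{fmt(self.f1)}"


def _label_sets(labels: np.ndarray) -> dict[int, np.ndarray]:
    labels = np.asarray(labels)
    return {int(v): labels == v for v in np.unique(labels) if v > 0}


def match_instances(
    pred_labels: np.ndarray, truth_labels: np.ndarray, iou_complete: float = 0.7
) -> DetectionCounts:
    """Greedy one-to-one IoU matching of predicted vs ground-truth cells.

    Pairs are matched in order of descending IoU among pairs reaching
    ``iou_complete``; a matched truth cell is a TP, an unmatched prediction
    an FP, an unmatched truth cell an FN.

    Parameters accept plain integer label maps (0 = background); pass
    ``CellInstanceSet.labels`` for pipeline output.
    """
    pred_labels = np.asarray(pred_labels)
    truth_labels = np.asarray(truth_labels)
    if pred_labels.shape != truth_labels.shape:
        raise ValueError("label maps must share a shape")
    preds = _label_sets(pred_labels)
    truths = _label_sets(truth_labels)
    if not preds or not truths:
        return DetectionCounts(tp=0, fp=len(preds), fn=len(truths))

    candidates = []
    for t_id, t_mask in truths.items():
        overlapping = np.unique(pred_labels[t_mask])
        for p_id in (int(v) for v in overlapping if v > 0):
            p_mask = preds[p_id]
            inter = np.logical_and(t_mask, p_mask).sum()
            union = t_mask.sum() + p_mask.sum() - inter
            iou = inter / union
            if iou >= iou_complete:
                candidates.append((iou, p_id, t_id))
    candidates.sort(key=lambda t: -t[0])

    used_p: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _iou, p_id, t_id in candidates:
        if p_id in used_p or t_id in used_t:
            continue
        used_p.add(p_id)
        used_t.add(t_id)
        tp += 1
    return DetectionCounts(tp=tp, fp=len(preds) - tp, fn=len(truths) - tp)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (all on the 0-100 scale)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def compute_metrics(counts: DetectionCounts) -> MetricReport:
    """TPR, PPV, F1 and FDR (percent, rounded to two decimals).

    A metric whose denominator is zero is reported as ``None``; all-zero
    counts yield an empty report with a warning.
    """
    if counts.tp == counts.fp == counts.fn == 0:
        warnings.warn("all detection counts are zero; metrics are undefined")
        return MetricReport(None, None, None, None)
    tpr = ppv = f1 = fdr = None
    if counts.tp + counts.fn > 0:
        tpr = 100.0 * counts.tp / (counts.tp + counts.fn)
    if counts.tp + counts.fp > 0:
        ppv = 100.0 * counts.tp / (counts.tp + counts.fp)
        fdr = 100.0 * counts.fp / (counts.tp + counts.fp)
    if tpr is not None and ppv is not None and (tpr + ppv) > 0:
        f1 = f1_from_precision_recall(ppv, tpr)
    rnd = lambda v: None if v is None else round(v, 2)
    return MetricReport(tpr=rnd(tpr), ppv=rnd(ppv), f1=rnd(f1), fdr=rnd(fdr))
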
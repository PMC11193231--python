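"""Detection and segmentation evaluation mathematics.

Implements the standard object-detection validation metrics: greedy
one-to-one matching of predictions to ground truth at an IoU threshold,
per-class average precision with all-point interpolation, mAP50 (and the
mAP50-95 sweep), micro-averaged precision/recall, a confusion matrix with an
explicit background row/column, and pixelwise segmentation IoU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .geometry import ClassTaxonomy, Detection, box_iou
from .io import MaskImage

__all__ = [
    "MatchSet",
    "EvalSummary",
    "ConfusionMatrix",
    "match_detections",
    "average_precision",
    "map50",
    "map50_95",
    "confusion_matrix",
    "mask_iou",
    "mean_mask_iou",
]


@dataclass
class MatchSet:
    """Result of one-to-one prediction/truth matching at an IoU threshold."""

    matches: list[tuple[Detection, Detection]]  # (prediction, truth) pairs
    false_positives: list[Detection]
    false_negatives: list[Detection]
    iou_threshold: float

    @property
    def n_tp(self) -> int:
        return len(self.matches)


@dataclass
class EvalSummary:
    """Detector validation metrics in the usual report shape."""

    per_class_ap: dict[str, float]
    map50: float
    precision: float
    recall: float
    iou_threshold: float = 0.5


def _conf_order(preds: Sequence[Detection]) -> list[Detection]:
    # Descending confidence; ties keep input order.
    return [p for _, p in sorted(enumerate(preds), key=lambda ip: (-ip[1].confidence, ip[0]))]


def match_detections(
    preds: Sequence[Detection],
    truths: Sequence[Detection],
    iou_threshold: float = 0.5,
) -> MatchSet:
    """Greedy class-strict one-to-one matching within a frame.

    Predictions are visited in descending confidence; each takes the
    highest-IoU still-unmatched truth of the *same class* with IoU >=
    ``iou_threshold``.  Leftover predictions are false positives, leftover
    truths false negatives.
    """
    matched_truth = [False] * len(truths)
    matches: list[tuple[Detection, Detection]] = []
    false_positives: list[Detection] = []
    for pred in _conf_order(preds):
        best_iou = 0.0
        best_j: Optional[int] = None
        for j, truth in enumerate(truths):
            if matched_truth[j] or truth.class_label != pred.class_label:
                continue
            iou = box_iou(pred.box, truth.box)
            if iou >= iou_threshold and iou > best_iou:
                best_iou, best_j = iou, j
        if best_j is not None:
            matched_truth[best_j] = True
            matches.append((pred, truths[best_j]))
        else:
            false_positives.append(pred)
    false_negatives = [t for j, t in enumerate(truths) if not matched_truth[j]]
    return MatchSet(matches, false_positives, false_negatives, iou_threshold)


def _tp_flags_for_class(
    preds_by_frame: Sequence[Sequence[Detection]],
    truths_by_frame: Sequence[Sequence[Detection]],
    class_label: str,
    iou_threshold: float,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pooled confidence-ranked TP/FP flags for one class across frames."""
    scored: list[tuple[float, int, bool]] = []  # (-conf, running order, is_tp)
    order = 0
    n_truth = 0
    for preds, truths in zip(preds_by_frame, truths_by_frame):
        cls_truths = [t for t in truths if t.class_label == class_label]
        n_truth += len(cls_truths)
        cls_preds = [p for p in preds if p.class_label == class_label]
        matched = [False] * len(cls_truths)
        for pred in _conf_order(cls_preds):
            best_iou, best_j = 0.0, None
            for j, truth in enumerate(cls_truths):
                if matched[j]:
                    continue
                iou = box_iou(pred.box, truth.box)
                if iou >= iou_threshold and iou > best_iou:
                    best_iou, best_j = iou, j
            is_tp = best_j is not None
            if is_tp:
                matched[best_j] = True
            scored.append((-pred.confidence, order, is_tp))
            order += 1
    scored.sort()
    confs = np.array([-s[0] for s in scored])
    tps = np.array([s[2] for s in scored], dtype=bool)
    return confs, tps, n_truth


def _ap_from_flags(tps: np.ndarray, n_truth: int) -> float:
    """All-point interpolated AP from confidence-ranked TP/FP flags."""
    if n_truth == 0:
        raise ValueError("AP undefined for a class with no ground truth")
    if tps.size == 0:
        return 0.0
    tp_cum = np.cumsum(tps)
    fp_cum = np.cumsum(~tps)
    recall = tp_cum / n_truth
    precision = tp_cum / (tp_cum + fp_cum)
    # Precision envelope (monotone non-increasing from the right), then the
    # exact area under the resulting staircase.
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - r_prev) * p
        r_prev = r
    return float(ap)


def average_precision(
    preds_by_frame: Sequence[Sequence[Detection]],
    truths_by_frame: Sequence[Sequence[Detection]],
    class_label: str,
    iou_threshold: float = 0.5,
) -> float:
    """All-point interpolated average precision for one class.

    Predictions are pooled across frames, ranked by confidence (ties by input
    order), matched greedily within their frame, and the area under the
    precision envelope of the resulting PR staircase is returned.  AP is 0
    when the class has truths but no true positives; a class absent from the
    truth raises (exclude it from the mean instead of scoring it 0).
    """
    _, tps, n_truth = _tp_flags_for_class(
        preds_by_frame, truths_by_frame, class_label, iou_threshold
    )
    return _ap_from_flags(tps, n_truth)


def map50(
    preds_by_frame: Sequence[Sequence[Detection]],
    truths_by_frame: Sequence[Sequence[Detection]],
    taxonomy: ClassTaxonomy,
    iou_threshold: float = 0.5,
) -> EvalSummary:
    """mAP at one IoU threshold plus micro-averaged precision/recall.

    The mean runs over the classes present in the ground truth; classes the
    detector never had to find do not dilute (or inflate) the mean.
    """
    if len(preds_by_frame) != len(truths_by_frame):
        raise ValueError("preds_by_frame and truths_by_frame differ in length")
    truth_classes = [
        lbl
        for lbl in taxonomy.labels
        if any(t.class_label == lbl for frame in truths_by_frame for t in frame)
    ]
    if not truth_classes:
        raise ValueError("nothing to evaluate: no ground-truth detections")

    per_class_ap: dict[str, float] = {}
    total_tp = total_pred = total_truth = 0
    for lbl in truth_classes:
        _, tps, n_truth = _tp_flags_for_class(
            preds_by_frame, truths_by_frame, lbl, iou_threshold
        )
        per_class_ap[lbl] = _ap_from_flags(tps, n_truth)
        total_tp += int(tps.sum())
        total_pred += int(tps.size)
        total_truth += n_truth
    # Predictions of classes with no ground truth anywhere still count as FPs
    # in the micro-averaged precision.
    for frame in preds_by_frame:
        total_pred += sum(1 for p in frame if p.class_label not in truth_classes)

    return EvalSummary(
        per_class_ap=per_class_ap,
        map50=float(np.mean(list(per_class_ap.values()))),
        precision=total_tp / total_pred if total_pred else 0.0,
        recall=total_tp / total_truth,
        iou_threshold=iou_threshold,
    )


def map50_95(
    preds_by_frame: Sequence[Sequence[Detection]],
    truths_by_frame: Sequence[Sequence[Detection]],
    taxonomy: ClassTaxonomy,
) -> float:
    """Mean of mAP over IoU thresholds 0.50:0.05:0.95 (the COCO-style sweep)."""
    thresholds = np.arange(0.5, 0.96, 0.05)
    return float(
        np.mean(
            [map50(preds_by_frame, truths_by_frame, taxonomy, t).map50 for t in thresholds]
        )
    )


@dataclass
class ConfusionMatrix:
    """(n_classes + 1)^2 counts; the extra last index is background."""

    counts: np.ndarray  # rows: true class, cols: predicted class
    labels: tuple[str, ...]  # class labels, background appended implicitly
    iou_threshold: float
    conf_threshold: float

    @property
    def background_index(self) -> int:
        return len(self.labels)

    def cell(self, true_label: Optional[str], pred_label: Optional[str]) -> int:
        i = self.labels.index(true_label) if true_label is not None else self.background_index
        j = self.labels.index(pred_label) if pred_label is not None else self.background_index
        return int(self.counts[i, j])


def confusion_matrix(
    preds_by_frame: Sequence[Sequence[Detection]],
    truths_by_frame: Sequence[Sequence[Detection]],
    taxonomy: ClassTaxonomy,
    iou_threshold: float = 0.5,
    conf_threshold: float = 0.25,
) -> ConfusionMatrix:
    """Detection confusion matrix with a background row and column.

    Predictions below ``conf_threshold`` are dropped.  Matching is
    class-agnostic and purely spatial, so a well-localized box with the wrong
    label lands in the off-diagonal (true, predicted) cell; unmatched truths
    count against (true, background) and unmatched predictions against
    (background, predicted).
    """
    n = len(taxonomy)
    counts = np.zeros((n + 1, n + 1), dtype=np.int64)
    for preds, truths in zip(preds_by_frame, truths_by_frame):
        live = [p for p in preds if p.confidence >= conf_threshold]
        matched = [False] * len(truths)
        for pred in _conf_order(live):
            best_iou, best_j = 0.0, None
            for j, truth in enumerate(truths):
                if matched[j]:
                    continue
                iou = box_iou(pred.box, truth.box)
                if iou >= iou_threshold and iou > best_iou:
                    best_iou, best_j = iou, j
            pi = taxonomy.index(pred.class_label)
            if best_j is not None:
                matched[best_j] = True
                counts[taxonomy.index(truths[best_j].class_label), pi] += 1
            else:
                counts[n, pi] += 1  # spurious prediction
        for j, truth in enumerate(truths):
            if not matched[j]:
                counts[taxonomy.index(truth.class_label), n] += 1  # missed truth
    return ConfusionMatrix(
        counts=counts,
        labels=taxonomy.labels,
        iou_threshold=iou_threshold,
        conf_threshold=conf_threshold,
    )


def mask_iou(pred: MaskImage, truth: MaskImage) -> float:
    """Pixelwise intersection over union of two binary masks.

    Two empty masks score 1 (the empty prediction is vacuously correct).
    """
    if pred.pixels.shape != truth.pixels.shape:
        raise ValueError(
            f"mask shapes differ: {pred.pixels.shape} vs {truth.pixels.shape}"
        )
    inter = np.logical_and(pred.pixels, truth.pixels).sum()
    union = np.logical_or(pred.pixels, truth.pixels).sum()
    if union == 0:
        return 1.0
    return float(inter / union)


def mean_mask_iou(preds: Sequence[MaskImage], truths: Sequence[MaskImage]) -> float:
    """Arithmetic mean of per-image mask IoU."""
    if len(preds) != len(truths):
        raise ValueError("prediction and truth mask lists differ in length")
    if not preds:
        raise ValueError("nothing to evaluate: empty mask lists")
    return float(np.mean([mask_iou(p, t) for p, t in zip(preds, truths)]))
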
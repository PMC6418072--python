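"""Segmentation scoring: pixel-level metrics and per-granule detection.

Two metric families: (i) pixel accuracy, mean per-class accuracy and mean
region intersection-over-union computed from the 2-class confusion matrix;
(ii) object-level TP/FP/FN with precision, from a greedy one-to-one matching
of predicted to true instances in descending IoU order.  High pixel accuracy
can hide total detection failure when granules cover a small image fraction,
which is why both families are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ConfusionMatrix:
    """Pixel counts n[i, j]: true class i predicted as class j."""

    n: np.ndarray  # (2, 2) int64

    @classmethod
    def from_masks(cls, pred: np.ndarray, truth: np.ndarray) -> "ConfusionMatrix":
        if pred.shape != truth.shape:
            raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
        p = np.asarray(pred).astype(bool).ravel()
        t = np.asarray(truth).astype(bool).ravel()
        n = np.zeros((2, 2), dtype=np.int64)
        for i in (0, 1):
            for j in (0, 1):
                n[i, j] = np.count_nonzero((t == bool(i)) & (p == bool(j)))
        return cls(n)


@dataclass
class DetectionResult:
    tp: int
    fp: int
    fn: int
    precision: float
    precision_defined: bool  # False when there are no predictions at all
    matches: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0


def pixel_metrics(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float, float]:
    """(pixel_accuracy, mean_accuracy, mean_iu) for 2-class masks.

    With t_i the true pixel count of class i and n_ij the confusion counts:
    pixel_accuracy = sum_i n_ii / sum_i t_i;
    mean_accuracy  = mean over present classes of n_ii / t_i;
    mean_iu        = mean over present classes of n_ii / (t_i + sum_j n_ji - n_ii).
    Classes absent from the truth are excluded from the means.
    """
    cm = ConfusionMatrix.from_masks(pred, truth).n
    t = cm.sum(axis=1)
    pred_tot = cm.sum(axis=0)
    present = t > 0
    pixel_acc = float(np.diag(cm).sum() / t.sum())
    acc = np.diag(cm)[present] / t[present]
    mean_acc = float(acc.mean())
    denom = t[present] + pred_tot[present] - np.diag(cm)[present]
    iu = np.where(denom > 0, np.diag(cm)[present] / np.maximum(denom, 1), 0.0)
    mean_iu = float(iu.mean())
    return pixel_acc, mean_acc, mean_iu


def _pairwise_iou(pred: np.ndarray, truth: np.ndarray):
    """IoU for every (truth label, pred label) pair via the joint histogram."""
    kp = int(pred.max())
    kt = int(truth.max())
    if kp == 0 or kt == 0:
        return np.zeros((kt, kp)), kt, kp
    joint = np.zeros((kt + 1, kp + 1), dtype=np.int64)
    np.add.at(joint, (truth.ravel(), pred.ravel()), 1)
    t_area = joint.sum(axis=1)
    p_area = joint.sum(axis=0)
    inter = joint[1:, 1:].astype(float)
    union = t_area[1:, None] + p_area[None, 1:] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou, kt, kp


def match_instances(
    pred: np.ndarray, truth: np.ndarray, iou_threshold: float = 0.5
) -> DetectionResult:
    """Greedy one-to-one matching of predicted to true instances.

    Pairs are taken in descending IoU order; a pair with IoU >= threshold is
    a true positive.  Unmatched predictions are false positives, unmatched
    truths false negatives.  With no predictions at all, precision is
    reported as 0 and flagged undefined.
    """
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if not 0 < iou_threshold < 1:
        raise ValueError("iou_threshold must lie in (0, 1)")
    iou, kt, kp = _pairwise_iou(np.asarray(pred), np.asarray(truth))
    matches: list[tuple[int, int, float]] = []
    if kt and kp:
        order = np.argsort(iou, axis=None)[::-1]
        used_t = np.zeros(kt, dtype=bool)
        used_p = np.zeros(kp, dtype=bool)
        for flat in order:
            ti, pi = divmod(int(flat), kp)
            if iou[ti, pi] < iou_threshold:
                break
            if used_t[ti] or used_p[pi]:
                continue
            used_t[ti] = used_p[pi] = True
            matches.append((ti + 1, pi + 1, float(iou[ti, pi])))
    tp = len(matches)
    fp = kp - tp
    fn = kt - tp
    if tp + fp > 0:
        return DetectionResult(tp, fp, fn, tp / (tp + fp), True, matches)
    return DetectionResult(tp, fp, fn, 0.0, False, matches)
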
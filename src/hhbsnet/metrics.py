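"""Evaluation protocol: confusion matrix, the seven segmentation
metrics, per-image Dice, one-vs-rest ROC/AUC, run aggregation, and the
paired t-test.

All metrics are derived from a single K x K confusion matrix (rows =
reference class, columns = predicted class) accumulated over every
evaluated pixel.  Macro means skip classes whose denominator is
undefined (e.g. a class absent from both reference and prediction for
IoU), which matters on tiny synthetic scenes.
"""

from __future__ import annotations

import csv
import dataclasses
import math

import numpy as np
from scipy import stats

__all__ = [
    "ZeroVarianceError",
    "MetricsReport",
    "confusion_matrix",
    "segmentation_metrics",
    "dice_per_image",
    "roc_auc_ovr",
    "paired_t_test",
    "aggregate_runs",
]


class ZeroVarianceError(ValueError):
    """Raised when paired differences have no variance (t undefined)."""


SCALAR_METRICS = ("miou", "acc", "f1", "mean_recall", "precision", "dice",
                  "specificity")


@dataclasses.dataclass
class MetricsReport:
    """Macro metrics plus per-class breakdowns, all fractions in [0, 1].

    ``dice`` here is the macro per-class Dice computed from the global
    confusion-matrix counts (identical to macro F1 by construction);
    lesion-focused per-image Dice is computed separately by
    :func:`dice_per_image` and averaged by the evaluation driver.
    """

    miou: float
    acc: float
    f1: float
    mean_recall: float
    precision: float
    dice: float
    specificity: float
    per_class: dict[str, dict[int, float]]

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in SCALAR_METRICS}

    def to_text(self) -> str:
        lines = [f"{k} {getattr(self, k):.6f}" for k in SCALAR_METRICS]
        return "\n".join(lines) + "\n"

    def write_csv(self, path) -> None:
        classes = sorted({c for d in self.per_class.values() for c in d})
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["metric", "macro"] + [f"class_{c}" for c in classes])
            for name in SCALAR_METRICS:
                row = [name, f"{getattr(self, name):.6f}"]
                per = self.per_class.get(name, {})
                row += [f"{per[c]:.6f}" if c in per else "" for c in classes]
                writer.writerow(row)


def confusion_matrix(pred: np.ndarray, ref: np.ndarray, num_classes: int) -> np.ndarray:
    """Pixel counts, counts[r, c] = #(reference r predicted c)."""
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs ref {ref.shape}")
    for name, arr in (("pred", pred), ("ref", ref)):
        if arr.size and (arr.min() < 0 or arr.max() >= num_classes):
            raise ValueError(f"{name} labels outside 0..{num_classes - 1}")
    idx = ref.reshape(-1).astype(np.int64) * num_classes + pred.reshape(-1)
    counts = np.bincount(idx, minlength=num_classes * num_classes)
    return counts.reshape(num_classes, num_classes)


def segmentation_metrics(cm: np.ndarray) -> MetricsReport:
    """Derive the seven metrics from a confusion matrix."""
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    k = cm.shape[0]
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn

    per: dict[str, dict[int, float]] = {m: {} for m in
                                        ("iou", "precision", "recall", "f1",
                                         "dice", "specificity")}
    for c in range(k):
        if tp[c] + fp[c] + fn[c] > 0:
            per["iou"][c] = tp[c] / (tp[c] + fp[c] + fn[c])
            per["dice"][c] = 2 * tp[c] / (2 * tp[c] + fp[c] + fn[c])
        if tp[c] + fp[c] > 0:
            per["precision"][c] = tp[c] / (tp[c] + fp[c])
        if tp[c] + fn[c] > 0:
            per["recall"][c] = tp[c] / (tp[c] + fn[c])
        if c in per["precision"] and c in per["recall"]:
            p, r = per["precision"][c], per["recall"][c]
            per["f1"][c] = 0.0 if p + r == 0 else 2 * p * r / (p + r)
        if tn[c] + fp[c] > 0:
            per["specificity"][c] = tn[c] / (tn[c] + fp[c])

    def macro(name: str) -> float:
        vals = list(per[name].values())
        return float(np.mean(vals)) if vals else float("nan")

    return MetricsReport(
        miou=macro("iou"),
        acc=float(tp.sum() / total),
        f1=macro("f1"),
        mean_recall=macro("recall"),
        precision=macro("precision"),
        dice=macro("dice"),
        specificity=macro("specificity"),
        per_class=per,
    )


def dice_per_image(pred: np.ndarray, ref: np.ndarray, cls: int) -> float:
    """2|P∩R| / (|P|+|R|) for one class in one image; 1.0 if both empty."""
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    p = pred == cls
    r = ref == cls
    denom = p.sum() + r.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, r).sum() / denom)


def roc_auc_ovr(probs: np.ndarray, ref: np.ndarray) -> dict[int, float | None]:
    """One-vs-rest AUC per class from a [K, ...] probability array.

    Sweeps all thresholds over each class's probability channel
    (trapezoidal integration over the resulting (FPR, TPR) staircase,
    which handles ties by grouping equal scores).  Classes with no
    positive or no negative pixels get ``None``.
    """
    probs = np.asarray(probs, dtype=np.float64)
    ref = np.asarray(ref)
    k = probs.shape[0]
    if probs.shape[1:] != ref.shape:
        raise ValueError(f"probs {probs.shape} do not align with ref {ref.shape}")
    out: dict[int, float | None] = {}
    flat_ref = ref.reshape(-1)
    for c in range(k):
        scores = probs[c].reshape(-1)
        pos = flat_ref == c
        n_pos = int(pos.sum())
        n_neg = pos.size - n_pos
        if n_pos == 0 or n_neg == 0:
            out[c] = None
            continue
        order = np.argsort(-scores, kind="stable")
        s_sorted = scores[order]
        pos_sorted = pos[order].astype(np.float64)
        tp = np.cumsum(pos_sorted)
        fp = np.cumsum(1.0 - pos_sorted)
        # keep only the last point of each tied-score run
        distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
        tpr = np.r_[0.0, tp[distinct] / n_pos]
        fpr = np.r_[0.0, fp[distinct] / n_neg]
        out[c] = float(np.trapezoid(tpr, fpr))
    return out


def paired_t_test(a, b) -> tuple[float, float]:
    """Paired two-sided t-test on matched score sequences.

    Returns (t, p) with t = mean(d) / (sd(d)/sqrt(n)), df = n - 1, sd
    with the n-1 denominator, and p from the exact t distribution.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_t_test expects two equal-length 1-D sequences")
    n = a.size
    if n < 2:
        raise ValueError("need at least two paired observations")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ZeroVarianceError("paired differences have zero variance")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def aggregate_runs(reports: list[MetricsReport]) -> dict[str, tuple[float, float]]:
    """Per-metric sample mean and standard deviation (n-1) over runs."""
    if len(reports) < 2:
        raise ValueError("need at least two runs to aggregate")
    out = {}
    for name in SCALAR_METRICS:
        vals = np.array([getattr(r, name) for r in reports], dtype=np.float64)
        out[name] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out
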
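"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive (nested loops, pairwise
enumeration) and shares no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np


def naive_conv2d(x, w, b=None, stride=1, padding=0, dilation=1, groups=1):
    """Direct nested-loop 2-D cross-correlation on [C, H, W]."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    C, H, W = x.shape
    Cout, Cin_g, kH, kW = w.shape
    xp = np.zeros((C, H + 2 * padding, W + 2 * padding))
    xp[:, padding:padding + H, padding:padding + W] = x
    OH = (xp.shape[1] - (kH - 1) * dilation - 1) // stride + 1
    OW = (xp.shape[2] - (kW - 1) * dilation - 1) // stride + 1
    out = np.zeros((Cout, OH, OW))
    group_size_out = Cout // groups
    for co in range(Cout):
        g = co // group_size_out
        for oy in range(OH):
            for ox in range(OW):
                acc = 0.0
                for ci in range(Cin_g):
                    c_in = g * Cin_g + ci
                    for ky in range(kH):
                        for kx in range(kW):
                            iy = oy * stride + ky * dilation
                            ix = ox * stride + kx * dilation
                            acc += xp[c_in, iy, ix] * w[co, ci, ky, kx]
                out[co, oy, ox] = acc
        if b is not None:
            out[co] += b[co]
    return out


def pairwise_auc(scores, labels):
    """Mann–Whitney AUC: concordant pairs plus half ties."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def tally_confusion(pred, ref, k):
    """Pixel-by-pixel confusion-matrix tally."""
    cm = np.zeros((k, k), dtype=np.int64)
    for r, p in zip(np.asarray(ref).reshape(-1), np.asarray(pred).reshape(-1)):
        cm[r, p] += 1
    return cm


def metrics_from_masks(pred, ref, k):
    """Per-class and macro metrics computed straight from definitions."""
    pred = np.asarray(pred).reshape(-1)
    ref = np.asarray(ref).reshape(-1)
    total = ref.size
    per = {"iou": {}, "precision": {}, "recall": {}, "f1": {},
           "dice": {}, "specificity": {}}
    correct = 0
    for c in range(k):
        tp = int(np.sum((pred == c) & (ref == c)))
        fp = int(np.sum((pred == c) & (ref != c)))
        fn = int(np.sum((pred != c) & (ref == c)))
        tn = total - tp - fp - fn
        correct += tp
        if tp + fp + fn > 0:
            per["iou"][c] = tp / (tp + fp + fn)
            per["dice"][c] = 2 * tp / (2 * tp + fp + fn)
        if tp + fp > 0:
            per["precision"][c] = tp / (tp + fp)
        if tp + fn > 0:
            per["recall"][c] = tp / (tp + fn)
        if c in per["precision"] and c in per["recall"]:
            p, r = per["precision"][c], per["recall"][c]
            per["f1"][c] = 0.0 if p + r == 0 else 2 * p * r / (p + r)
        if tn + fp > 0:
            per["specificity"][c] = tn / (tn + fp)

    def macro(name):
        vals = list(per[name].values())
        return sum(vals) / len(vals) if vals else float("nan")

    return {
        "miou": macro("iou"),
        "acc": correct / total,
        "f1": macro("f1"),
        "mean_recall": macro("recall"),
        "precision": macro("precision"),
        "dice": macro("dice"),
        "specificity": macro("specificity"),
        "per_class": per,
    }


def finite_difference_grad(f, x, eps=1e-6):
    """Central finite differences of a scalar function of an array."""
    x = np.asarray(x, dtype=np.float64)
    grad = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp = x.copy()
        xp[idx] += eps
        xm = x.copy()
        xm[idx] -= eps
        grad[idx] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return grad


def point_in_polygon(px, py, vertices):
    """Ray-casting point-in-polygon test (crossing number)."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside
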
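"""Multi-label evaluation metrics.

Accuracy is reported in two modes because the bitwise ratio
(TP+TN)/(TP+FN+FP+TN) over all instance-label positions and the
exact-match (subset) rate are both in common use and reports must say
which they quote; bitwise is the default.  Jaccard similarity is the
instance-averaged intersection-over-union of label sets (an instance
where both sets are empty scores 1, the limit convention).  Hamming loss
is the fraction of misclassified label positions, so bitwise accuracy +
Hamming loss = 1 identically.  Precision/recall/F1 support micro
(pooled counts, default) and macro (per-label average) averaging, with
the 0/0 -> 0 convention.
"""

from __future__ import annotations

import json

import numpy as np


def _validate(Y_true, Y_pred):
    Y_true = np.asarray(Y_true)
    Y_pred = np.asarray(Y_pred)
    if Y_true.shape != Y_pred.shape or Y_true.ndim != 2:
        raise ValueError("Y_true and Y_pred must be equal-shape 2-D arrays")
    for M in (Y_true, Y_pred):
        if not np.isin(M, (0, 1)).all():
            raise ValueError("entries must be binary")
    return Y_true.astype(int), Y_pred.astype(int)


def hamming_loss(Y_true, Y_pred) -> float:
    """Fraction of instance-label positions where prediction and truth disagree."""
    Y_true, Y_pred = _validate(Y_true, Y_pred)
    return float(np.mean(Y_true != Y_pred))


def jaccard(Y_true, Y_pred) -> float:
    """Mean over instances of |pred AND true| / |pred OR true|."""
    Y_true, Y_pred = _validate(Y_true, Y_pred)
    inter = np.sum(Y_true & Y_pred, axis=1)
    union = np.sum(Y_true | Y_pred, axis=1)
    per = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return float(np.mean(per))


def accuracy(Y_true, Y_pred, mode: str = "bitwise") -> float:
    """'bitwise': (TP+TN)/(TP+FN+FP+TN) over all positions;
    'subset': exact-match rate of whole label sets."""
    Y_true, Y_pred = _validate(Y_true, Y_pred)
    if mode == "bitwise":
        return float(np.mean(Y_true == Y_pred))
    if mode == "subset":
        return float(np.mean(np.all(Y_true == Y_pred, axis=1)))
    raise ValueError(f"unknown mode {mode!r}")


def precision_recall_f1(Y_true, Y_pred, averaging: str = "micro"):
    """(precision, recall, F1); F1 = 2PR/(P+R), 0 when P + R = 0."""
    Y_true, Y_pred = _validate(Y_true, Y_pred)
    tp = (Y_true & Y_pred).sum(axis=0).astype(float)
    fp = (~Y_true.astype(bool) & Y_pred.astype(bool)).sum(axis=0).astype(float)
    fn = (Y_true.astype(bool) & ~Y_pred.astype(bool)).sum(axis=0).astype(float)

    def prf(tp_, fp_, fn_):
        p = tp_ / (tp_ + fp_) if tp_ + fp_ > 0 else 0.0
        r = tp_ / (tp_ + fn_) if tp_ + fn_ > 0 else 0.0
        f = 2 * p * r / (p + r) if p + r > 0 else 0.0
        return p, r, f

    if averaging == "micro":
        return prf(tp.sum(), fp.sum(), fn.sum())
    if averaging == "macro":
        trip = np.array([prf(a, b, c) for a, b, c in zip(tp, fp, fn)])
        return tuple(trip.mean(axis=0))
    raise ValueError(f"unknown averaging {averaging!r}")


def per_label_confusion(Y_true, Y_pred) -> list[dict]:
    """For each label: {TP, FP, FN, TN} instance counts (they sum to n)."""
    Y_true, Y_pred = _validate(Y_true, Y_pred)
    out = []
    for j in range(Y_true.shape[1]):
        t, p = Y_true[:, j].astype(bool), Y_pred[:, j].astype(bool)
        out.append({"TP": int(np.sum(t & p)), "FP": int(np.sum(~t & p)),
                    "FN": int(np.sum(t & ~p)), "TN": int(np.sum(~t & ~p))})
    return out


def roc_points(Y_true, P, n_thresholds: int = 101) -> list[dict]:
    """Per-label (threshold, TPR, FPR) sweep for ROC plotting."""
    Y_true = np.asarray(Y_true).astype(bool)
    P = np.asarray(P, dtype=float)
    rows = []
    for j in range(Y_true.shape[1]):
        t = Y_true[:, j]
        for thr in np.linspace(0.0, 1.0, n_thresholds):
            pred = P[:, j] >= thr
            tpr = np.sum(pred & t) / max(np.sum(t), 1)
            fpr = np.sum(pred & ~t) / max(np.sum(~t), 1)
            rows.append({"label": j, "threshold": float(thr),
                         "tpr": float(tpr), "fpr": float(fpr)})
    return rows


def evaluate(Y_true, Y_pred, accuracy_mode: str = "bitwise") -> dict:
    """Full metric report (states its accuracy mode)."""
    p, r, f = precision_recall_f1(Y_true, Y_pred, "micro")
    pm, rm, fm = precision_recall_f1(Y_true, Y_pred, "macro")
    return {
        "accuracy": accuracy(Y_true, Y_pred, accuracy_mode),
        "accuracy_mode": accuracy_mode,
        "subset_accuracy": accuracy(Y_true, Y_pred, "subset"),
        "hamming_loss": hamming_loss(Y_true, Y_pred),
        "jaccard": jaccard(Y_true, Y_pred),
        "precision": p, "recall": r, "f1": f,
        "precision_macro": pm, "recall_macro": rm, "f1_macro": fm,
        "per_label_confusion": per_label_confusion(Y_true, Y_pred),
    }


def write_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
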
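"""Evaluation metrics: top-k accuracy, thresholded metrics, AUPRC.

Top-k accuracy for a class with ``n_true`` true sites takes the
``k * n_true`` highest-scoring positions for that class and reports the
fraction that are true sites (so with 10 true sites per class, k=1 examines
the top 10 donor and top 10 acceptor predictions — 20 in total, and k=2
examines 40). Score ties are broken by position index, deterministically.

Thresholded metrics use the standard definitions — precision
TP/(TP+FP), recall TP/(TP+FN), accuracy (TP+TN)/total, F1 the harmonic
mean — at a strict threshold (score must exceed it). Zero-denominator
cases return 0 with a warning.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "topk_class_accuracy",
    "topk_accuracy",
    "threshold_metrics",
    "threshold_metrics_per_class",
    "auprc",
    "MetricsReport",
    "evaluate_predictions",
]

CLASS_NAMES = {1: "acceptor", 2: "donor"}


def topk_class_accuracy(scores: np.ndarray, true_positions, k: int = 1) -> float | None:
    """Top-k accuracy for one class from a per-position score vector.

    Returns None (with a warning) when there are no true sites.
    """
    true_set = set(int(p) for p in true_positions)
    n_true = len(true_set)
    if n_true == 0:
        logger.warning("no true sites for this class; top-k accuracy skipped")
        return None
    order = np.argsort(-np.asarray(scores), kind="stable")
    top = order[: k * n_true]
    hits = sum(1 for p in top if int(p) in true_set)
    return hits / (k * n_true)


def topk_accuracy(probabilities: np.ndarray, labels: np.ndarray, k: int = 1) -> dict[str, float | None]:
    """Per-class (acceptor, donor) top-k accuracy from probability/label tracks."""
    p = probabilities.reshape(-1, probabilities.shape[-1])
    y = labels.reshape(-1, labels.shape[-1])
    valid = y.sum(axis=1) > 0
    p, y = p[valid], y[valid]
    out: dict[str, float | None] = {}
    for idx, name in CLASS_NAMES.items():
        true_positions = np.nonzero(y[:, idx] == 1)[0]
        out[name] = topk_class_accuracy(p[:, idx], true_positions, k)
    return out


def threshold_metrics(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> dict:
    """Binary accuracy/precision/recall/F1 at a strict score threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pred = scores > threshold  # ties at the threshold are negative calls
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            logger.warning("%s undefined (zero denominator); reported as 0", name)
            return 0.0
        return num / den

    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        logger.warning("F1 undefined (precision + recall = 0); reported as 0")
        f1 = 0.0
    return {
        "accuracy": (tp + tn) / max(tp + fp + tn + fn, 1),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
    }


def threshold_metrics_per_class(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict[str, dict]:
    p = probabilities.reshape(-1, probabilities.shape[-1])
    y = labels.reshape(-1, labels.shape[-1])
    valid = y.sum(axis=1) > 0
    p, y = p[valid], y[valid]
    return {
        name: threshold_metrics(p[:, idx], y[:, idx] == 1, threshold)
        for idx, name in CLASS_NAMES.items()
    }


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve over all score thresholds."""
    labels = np.asarray(labels).astype(int)
    if labels.sum() == 0:
        raise ValueError("AUPRC undefined with no positive labels")
    from sklearn.metrics import average_precision_score

    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


class MetricsReport(dict):
    """Plain dict of per-class metrics; kept as a type for readability."""


def evaluate_predictions(
    probabilities: np.ndarray,
    labels: np.ndarray,
    k: int = 1,
    threshold: float = 0.5,
) -> MetricsReport:
    """Combined report: top-k, thresholded metrics and AUPRC per class."""
    report = MetricsReport()
    report["topk"] = topk_accuracy(probabilities, labels, k)
    report["threshold"] = threshold_metrics_per_class(probabilities, labels, threshold)
    p = probabilities.reshape(-1, probabilities.shape[-1])
    y = labels.reshape(-1, labels.shape[-1])
    valid = y.sum(axis=1) > 0
    p, y = p[valid], y[valid]
    report["auprc"] = {}
    for idx, name in CLASS_NAMES.items():
        try:
            report["auprc"][name] = auprc(p[:, idx], y[:, idx] == 1)
        except ValueError:
            report["auprc"][name] = None
    return report
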
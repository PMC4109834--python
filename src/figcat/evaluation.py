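"""Confusion matrices and per-class precision / recall / F-score."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ConfusionMatrix:
    """``C x C`` counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        C = len(self.labels)
        if self.counts.shape != (C, C):
            raise ValueError("counts must be C x C with C = len(labels)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        tot = self.total
        return float(np.trace(self.counts) / tot) if tot else 0.0


def confusion(true, pred, labels: list[str] | None = None) -> ConfusionMatrix:
    """Tally a confusion matrix from parallel label sequences.

    ``labels`` fixes the class order; when omitted it is the sorted union
    of observed labels.  A label outside the given order is an error.
    """
    true, pred = list(true), list(pred)
    if len(true) != len(pred):
        raise ValueError("true and pred must have equal length")
    if labels is None:
        labels = sorted(set(true) | set(pred))
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(true, pred):
        if t not in index or p not in index:
            raise ValueError(f"unknown label: {t if t not in index else p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, labels=list(labels))


def metrics(cm: ConfusionMatrix) -> dict[str, dict[str, float]]:
    """Per-class TP/FP/FN and precision, recall, F-score.

    ``precision = TP/(TP+FP)``, ``recall = TP/(TP+FN)``,
    ``F = 2PR/(P+R)``; any 0/0 is reported as 0.  Values are kept at full
    precision; display rounding is left to the caller.
    """
    out = {}
    counts = cm.counts
    for i, lab in enumerate(cm.labels):
        tp = int(counts[i, i])
        fp = int(counts[:, i].sum() - tp)
        fn = int(counts[i, :].sum() - tp)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[lab] = {
            "TP": tp,
            "FP": fp,
            "FN": fn,
            "precision": prec,
            "recall": rec,
            "fscore": f,
        }
    return out


def report(cm: ConfusionMatrix, decimals: int = 4) -> dict:
    """JSON-ready report: confusion matrix plus the per-class metric table.

    Displayed values are rounded to ``decimals`` places (round-half-even).
    """
    table = {
        lab: {
            k: (round(v, decimals) if isinstance(v, float) else v)
            for k, v in row.items()
        }
        for lab, row in metrics(cm).items()
    }
    return {
        "labels": cm.labels,
        "confusion": cm.counts.tolist(),
        "accuracy": round(cm.accuracy(), decimals),
        "per_class": table,
    }
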
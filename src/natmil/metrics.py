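"""Slide-level evaluation metrics: rank-based AUC, accuracy at a 0.5
probability threshold, and macro-averaged F1."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["MetricReport", "compute_metrics"]


@dataclass
class MetricReport:
    auc: float | None  # None when only one class is present
    acc: float
    macro_f1: float
    n_slides: int
    n_positive: int
    n_negative: int
    tp: int
    fp: int
    fn: int
    tn: int

    def as_dict(self):
        return {"auc": self.auc, "acc": self.acc, "macro_f1": self.macro_f1,
                "n_slides": self.n_slides, "n_positive": self.n_positive,
                "n_negative": self.n_negative}


def compute_metrics(labels, scores) -> MetricReport:
    """labels: binary {0,1}; scores: positive-class probabilities.

    AUC is the Mann–Whitney rank statistic (ties counted half); with a
    single class it is undefined and reported as None, never as 0.
    """
    labels = np.asarray(labels, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape or labels.ndim != 1 or len(labels) == 0:
        raise ValueError("labels and scores must be equal-length 1-D arrays")
    n = len(labels)
    n1 = int(labels.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        auc = None
    else:
        r = rankdata(scores)
        auc = float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))
    pred = (scores >= 0.5).astype(np.int64)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    acc = (tp + tn) / n
    f1s = []
    for cls_tp, cls_fp, cls_fn in ((tp, fp, fn), (tn, fn, fp)):
        denom = 2 * cls_tp + cls_fp + cls_fn
        f1s.append(0.0 if denom == 0 else 2 * cls_tp / denom)
    return MetricReport(auc=auc, acc=float(acc), macro_f1=float(np.mean(f1s)),
                        n_slides=n, n_positive=n1, n_negative=n0,
                        tp=tp, fp=fp, fn=fn, tn=tn)
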
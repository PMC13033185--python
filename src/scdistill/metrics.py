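"""Clustering evaluation: ARI, NMI, AMI and Hungarian-matched per-class F1.

Predicted cluster ids carry no meaning, so per-class precision/recall
require a cluster→class correspondence first; it is found by maximising the
total matched count over the confusion matrix (Hungarian assignment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    normalized_mutual_info_score,
)

__all__ = ["EvalReport", "evaluate"]


@dataclass
class EvalReport:
    ari: float
    nmi: float
    ami: float
    per_class_f1: dict
    confusion: np.ndarray  # truth classes × predicted clusters
    truth_classes: list
    pred_clusters: list

    def to_dict(self) -> dict:
        return {
            "ari": self.ari,
            "nmi": self.nmi,
            "ami": self.ami,
            "per_class_f1": {str(k): v for k, v in self.per_class_f1.items()},
        }


def evaluate(pred, truth) -> EvalReport:
    """Score a predicted labelling against ground truth."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    truth_classes = sorted(set(truth.tolist()))
    pred_clusters = sorted(set(pred.tolist()))
    t_idx = {c: i for i, c in enumerate(truth_classes)}
    p_idx = {c: i for i, c in enumerate(pred_clusters)}
    confusion = np.zeros((len(truth_classes), len(pred_clusters)), dtype=np.int64)
    for t, p in zip(truth, pred):
        confusion[t_idx[t], p_idx[p]] += 1
    # Hungarian: one-to-one cluster→class map maximising matched count
    rows, cols = linear_sum_assignment(-confusion)
    cluster_to_class = {c: r for r, c in zip(rows, cols)}
    mapped = np.array([cluster_to_class.get(p_idx[p], -1) for p in pred])
    truth_i = np.array([t_idx[t] for t in truth])
    per_class_f1 = {}
    for cls, i in t_idx.items():
        tp = int(((mapped == i) & (truth_i == i)).sum())
        fp = int(((mapped == i) & (truth_i != i)).sum())
        fn = int(((mapped != i) & (truth_i == i)).sum())
        denom = 2 * tp + fp + fn
        per_class_f1[cls] = 2 * tp / denom if denom else 0.0
    return EvalReport(
        ari=float(adjusted_rand_score(truth, pred)),
        nmi=float(normalized_mutual_info_score(truth, pred)),
        ami=float(adjusted_mutual_info_score(truth, pred)),
        per_class_f1=per_class_f1,
        confusion=confusion,
        truth_classes=truth_classes,
        pred_clusters=pred_clusters,
    )
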
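"""Evaluation of de-novo protein-family clusterings against reference labels.

A candidate clustering (e.g. SiLiX at one identity threshold) is scored
against reference domain assignments (e.g. TIGRFAM) over all unordered
pairs of *labeled* sequences: a pair sharing a label and a cluster is a
true positive, sharing a label but split across clusters a false
negative, and so on.  Thresholds are ranked by balanced accuracy,
(sensitivity + specificity) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics.cluster import pair_confusion_matrix

__all__ = ["ClusteringEvaluation", "pair_confusion", "balanced_accuracy",
           "evaluate_clustering", "select_threshold"]


@dataclass
class ClusteringEvaluation:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    singleton_count: int = 0
    degenerate: bool = False  # a confusion denominator was zero


def pair_confusion(clusters: dict[str, str],
                   labels: dict[str, str]) -> tuple[int, int, int, int]:
    """Pairwise (TP, FP, TN, FN) over sequences that carry a reference label.

    Sequences with several reference domains should be reduced to the
    first-listed one before calling.  Unlabeled sequences are ignored.
    """
    ids = [s for s in clusters if s in labels]
    if not ids:
        raise ValueError("no labeled sequences to score")
    y_label = pd.factorize(np.asarray([labels[s] for s in ids]))[0]
    y_clust = pd.factorize(np.asarray([clusters[s] for s in ids]))[0]
    # pair_confusion_matrix counts ordered pairs; rows = reference, cols
    # = clustering, index 1 = "pair together".
    m = pair_confusion_matrix(y_label, y_clust)
    tn, fp = int(m[0, 0]) // 2, int(m[0, 1]) // 2
    fn, tp = int(m[1, 0]) // 2, int(m[1, 1]) // 2
    return tp, fp, tn, fn


def balanced_accuracy(tp: int, fp: int, tn: int, fn: int
                      ) -> tuple[float, bool]:
    """(sensitivity + specificity) / 2 with a degeneracy flag.

    An undefined sensitivity (TP+FN = 0) or specificity (TN+FP = 0)
    contributes 0 to the average.  The flag marks any such case, and
    also the vacuous ones where a rate is zero because the clustering
    produced no true-positive or true-negative pairs at all.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("negative confusion counts")
    if tp + fp + tn + fn == 0:
        raise ValueError("all confusion counts are zero")
    sens = tp / (tp + fn) if tp + fn > 0 else 0.0
    spec = tn / (tn + fp) if tn + fp > 0 else 0.0
    degenerate = (tp + fn == 0 or tn + fp == 0
                  or (tp == 0 and fp > 0) or (tn == 0 and fn > 0)
                  or (tn == 0 and fp > 0) or (tp == 0 and fn > 0))
    return (sens + spec) / 2.0, degenerate


def evaluate_clustering(threshold: float, clusters: dict[str, str],
                        labels: dict[str, str]) -> ClusteringEvaluation:
    tp, fp, tn, fn = pair_confusion(clusters, labels)
    ba, flag = balanced_accuracy(tp, fp, tn, fn)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    sizes = pd.Series(list(clusters.values())).value_counts()
    return ClusteringEvaluation(
        threshold=threshold, tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec, balanced_accuracy=ba,
        singleton_count=int((sizes == 1).sum()), degenerate=flag,
    )


def select_threshold(evaluations: list[ClusteringEvaluation]) -> float:
    """Threshold with the best balanced accuracy; ties go to the lower
    (coarser) threshold."""
    if not evaluations:
        raise ValueError("no evaluations")
    best = max(evaluations,
               key=lambda e: (e.balanced_accuracy, -e.threshold))
    return best.threshold


def evaluations_to_frame(evals: list[ClusteringEvaluation]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in evals])
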
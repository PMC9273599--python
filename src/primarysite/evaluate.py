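"""Confusion matrices and recall / top-2 recall / precision summaries.

Per class: recall is the fraction of that class's samples whose top
prediction is correct; top-2 recall counts the true class among the two
highest probabilities; precision is the fraction correct among samples
predicted as the class. Micro-averaged recall equals overall accuracy;
micro-averaged precision is the micro-average over per-class precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def confusion_matrix(
    true_labels, predicted_labels, classes: list[str] | None = None
) -> pd.DataFrame:
    """Counts matrix with true classes as rows, predictions as columns."""
    true = pd.Series(list(true_labels))
    pred = pd.Series(list(predicted_labels))
    if classes is None:
        classes = sorted(set(true) | set(pred))
    unknown = (set(true) | set(pred)) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the class list: {sorted(unknown)}")
    mat = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(true, pred):
        mat.loc[t, p] += 1
    mat.index.name = "true"
    mat.columns.name = "predicted"
    return mat


def normalize_confusion(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize to the percentage of each true-class cohort."""
    totals = matrix.sum(axis=1)
    out = matrix.div(totals.replace(0, np.nan), axis=0) * 100.0
    return out.fillna(0.0)


@dataclass
class PerformanceSummary:
    per_class: pd.DataFrame  # class -> recall, top2_recall, precision, n
    micro_recall: float
    micro_top2_recall: float
    micro_precision: float
    confusion: pd.DataFrame


def performance_summary(
    true_labels, probability_matrix: pd.DataFrame
) -> PerformanceSummary:
    """Score predictions from a samples x classes probability matrix.

    The predicted class is the argmax (ties broken lexicographically).
    Samples whose probability row is entirely zero are degenerate: they count
    as incorrect for recall but are excluded from precision denominators.
    """
    probs = probability_matrix
    true = pd.Series(list(true_labels), index=probs.index)
    classes = list(probs.columns)
    unknown = set(true) - set(classes)
    if unknown:
        raise ValueError(f"true labels outside the class list: {sorted(unknown)}")

    arr = probs.to_numpy(dtype=float)
    degenerate = arr.max(axis=1) == 0
    if degenerate.any():
        logger.warning(
            "%d sample(s) have an all-zero probability row; counted as "
            "incorrect for recall, excluded from precision",
            int(degenerate.sum()),
        )
    ranks = []
    for i in range(arr.shape[0]):
        ranked = sorted(range(len(classes)), key=lambda j: (-arr[i, j], classes[j]))
        ranks.append([classes[j] for j in ranked])
    top1 = pd.Series([r[0] for r in ranks], index=probs.index)
    top2_hit = pd.Series(
        [t in r[:2] for t, r in zip(true, ranks)], index=probs.index
    )
    correct = (top1 == true) & ~degenerate
    top2_hit = top2_hit & ~degenerate

    rows = []
    for cls in classes:
        in_cls = true == cls
        n = int(in_cls.sum())
        recall = float(correct[in_cls].mean()) if n else np.nan
        top2 = float(top2_hit[in_cls].mean()) if n else np.nan
        predicted_as = (top1 == cls) & ~degenerate
        n_pred = int(predicted_as.sum())
        precision = (
            float((true[predicted_as] == cls).mean()) if n_pred else np.nan
        )
        rows.append((cls, recall, top2, precision, n))
    per_class = pd.DataFrame(
        rows, columns=["class", "recall", "top2_recall", "precision", "n"]
    ).set_index("class")

    n_total = len(true)
    micro_recall = float(correct.sum() / n_total)
    micro_top2 = float(top2_hit.sum() / n_total)
    # micro precision: pooled over classes that were actually predicted
    predicted_counts = pd.Series(
        [int(((top1 == c) & ~degenerate).sum()) for c in classes], index=classes
    )
    valid = predicted_counts > 0
    correct_counts = pd.Series(
        [int((correct & (true == c)).sum()) for c in classes], index=classes
    )
    micro_precision = float(
        correct_counts[valid].sum() / predicted_counts[valid].sum()
    )
    confusion = confusion_matrix(
        true[~degenerate], top1[~degenerate], classes=classes
    )
    return PerformanceSummary(
        per_class=per_class,
        micro_recall=micro_recall,
        micro_top2_recall=micro_top2,
        micro_precision=micro_precision,
        confusion=confusion,
    )
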
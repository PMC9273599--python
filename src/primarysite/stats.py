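"""Effect sizes, association tests and ranking metrics used across training.

Cliff's delta quantifies stochastic dominance between two numeric samples;
Cramer's V measures association strength in a 2x2 table; the area under the
precision-recall curve (average-precision formulation) scores a binary
ranking under class imbalance.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import fisher_exact, mannwhitneyu
from sklearn.metrics import average_precision_score


def cliffs_delta(x, y) -> float:
    """Cliff's delta between numeric samples x and y.

    delta = (#{x_i > y_j} - #{x_i < y_j}) / (n_x * n_y), in [-1, 1]; positive
    when x tends to dominate y. Computed in O((n+m) log(n+m)) via sorting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("cliffs_delta requires nonempty samples")
    ys = np.sort(y)
    greater = np.searchsorted(ys, x, side="left").sum()  # y_j < x_i
    less_eq = x.size * y.size - np.searchsorted(ys, x, side="right").sum()
    return float(greater - less_eq) / (x.size * y.size)


def cramers_v_2x2(table) -> float:
    """Cramer's V for a 2x2 count table: sqrt(chi2 / n), no continuity correction.

    Returns 0 when any margin is zero (no association measurable).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    n = t.sum()
    if n == 0:
        raise ValueError("table must have positive total count")
    a, b, c, d = t.ravel()
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        return 0.0
    chi2 = n * (a * d - b * c) ** 2 / margins
    return float(np.sqrt(chi2 / n))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve (average precision).

    Sum over descending unique score thresholds of (R_k - R_{k-1}) * P_k.
    Requires at least one positive label.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    if labels.sum() == 0:
        raise ValueError("auprc requires at least one positive label")
    return float(average_precision_score(labels, scores))


def rank_sum_p(case, control, alternative: str = "greater") -> float:
    """Wilcoxon rank-sum p-value (case vs control), tie-corrected.

    Uses the exact distribution for small tie-free samples and the normal
    approximation otherwise (scipy's automatic policy).
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("rank_sum_p requires nonempty samples")
    if np.all(case == case[0]) and np.all(control == control[0]) and case[0] == control[0]:
        return 1.0  # identical constant samples: no evidence either way
    alt = {"greater": "greater", "less": "less", "two-sided": "two-sided"}[alternative]
    return float(mannwhitneyu(case, control, alternative=alt, method="auto").pvalue)


def fisher_p(case_pos: int, case_neg: int, ctrl_pos: int, ctrl_neg: int,
             alternative: str = "greater") -> float:
    """Fisher exact p-value on the 2x2 table [[case_pos, ctrl_pos], [case_neg, ctrl_neg]]."""
    _, p = fisher_exact(
        [[case_pos, ctrl_pos], [case_neg, ctrl_neg]], alternative=alternative
    )
    return float(p)
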
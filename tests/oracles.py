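"""Independent oracles used by the test suite.

Each function recomputes a statistic from first principles by a different
route than the implementation it checks (pair enumeration, explicit
precision-recall integration, bounded least squares).
"""

from __future__ import annotations

import numpy as np


def brute_force_cliffs(x, y) -> float:
    """Cliff's delta by O(n*m) enumeration of all sample pairs."""
    x, y = np.asarray(x), np.asarray(y)
    greater = sum(xi > yj for xi in x for yj in y)
    less = sum(xi < yj for xi in x for yj in y)
    return (greater - less) / (len(x) * len(y))


def closed_form_cramers_v(table) -> float:
    """Cramer's V from the chi-square closed form for a 2x2 table."""
    t = np.asarray(table, dtype=float)
    a, b, c, d = t.ravel()
    n = t.sum()
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        return 0.0
    chi2 = n * (a * d - b * c) ** 2 / margins
    return float(np.sqrt(chi2 / n))


def brute_force_auprc(scores, labels) -> float:
    """Average precision by explicit PR integration over thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    thresholds = sorted(set(scores), reverse=True)
    total_pos = labels.sum()
    area = 0.0
    prev_recall = 0.0
    for t in thresholds:
        predicted = scores >= t
        tp = int((labels[predicted] == 1).sum())
        precision = tp / predicted.sum()
        recall = tp / total_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def isotonic_oracle(x, y) -> np.ndarray:
    """Monotone least-squares fit via bounded least squares on increments.

    Fitted values are parameterized as f_i = c + sum_{j<=i} d_j with d_j >= 0
    and c free, an independent route to the isotonic projection.
    """
    from scipy.optimize import lsq_linear

    order = np.argsort(x, kind="mergesort")
    y_sorted = np.asarray(y, dtype=float)[order]
    n = len(y_sorted)
    A = np.tril(np.ones((n, n)))
    A = np.hstack([np.ones((n, 1)), A[:, 1:]])
    lb = np.concatenate([[-np.inf], np.zeros(n - 1)])
    ub = np.full(n, np.inf)
    res = lsq_linear(A, y_sorted, bounds=(lb, ub), method="bvls", tol=1e-14)
    fitted = A @ res.x
    out = np.empty(n)
    out[order] = fitted
    return out
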
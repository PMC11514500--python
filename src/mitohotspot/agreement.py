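"""Agreement statistics between two mitotic-count readings.

Counts are compared as continuous variables by Pearson correlation; the
three-class BR mitotic scores are compared by linearly weighted Cohen's
kappa.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import br_mitotic_score

#: the three BR mitotic score categories, in order
BR_CATEGORIES = (1, 2, 3)


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p-value.

    The p-value comes from the exact null distribution of r under bivariate
    normality (equivalent to the t transform with n − 2 degrees of freedom).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs for a p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def confusion_matrix_3(scores_a, scores_b) -> np.ndarray:
    """3×3 confusion matrix of paired BR scores (rows: A, columns: B)."""
    a = np.asarray(scores_a, dtype=int)
    b = np.asarray(scores_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score lists must be equal-length 1-d sequences")
    for arr in (a, b):
        if not np.isin(arr, BR_CATEGORIES).all():
            raise ValueError("BR scores must be in {1, 2, 3}")
    cm = np.zeros((3, 3), dtype=np.int64)
    for i, j in zip(a - 1, b - 1):
        cm[i, j] += 1
    return cm


def weighted_kappa(cm) -> float:
    """Linearly weighted Cohen's kappa of a k×k confusion matrix.

    Agreement weights are w_ij = 1 − |i − j| / (k − 1);
    κ = (p_o,w − p_e,w) / (1 − p_e,w) with chance agreement from the margins.
    A matrix with no chance-corrected room (p_e,w = 1, e.g. all mass in one
    cell) returns 1.0, since no disagreement was observed.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.shape[0] < 2:
        raise ValueError("confusion matrix must be square, at least 2×2")
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    n = cm.sum()
    if n <= 0:
        raise ValueError("confusion matrix is empty")
    k = cm.shape[0]
    i, j = np.indices((k, k))
    w = 1.0 - np.abs(i - j) / (k - 1)
    po = float((w * cm).sum() / n)
    expected = np.outer(cm.sum(axis=1), cm.sum(axis=0)) / (n * n)
    pe = float((w * expected).sum())
    if 1.0 - pe < 1e-15:
        return 1.0
    return (po - pe) / (1.0 - pe)


def compare_counts(pairs: pd.DataFrame) -> dict:
    """Full agreement panel for a paired-MC table (columns mc_a, mc_b).

    Returns Pearson r and p on the raw counts, the 3×3 BR-score confusion
    matrix, and the linearly weighted kappa on the scores.
    """
    mc_a = pairs["mc_a"].to_numpy()
    mc_b = pairs["mc_b"].to_numpy()
    r, p = pearson_r(mc_a, mc_b)
    scores_a = [br_mitotic_score(int(v)) for v in mc_a]
    scores_b = [br_mitotic_score(int(v)) for v in mc_b]
    cm = confusion_matrix_3(scores_a, scores_b)
    return {
        "n": int(len(pairs)),
        "pearson_r": r,
        "pearson_p": p,
        "weighted_kappa": weighted_kappa(cm),
        "confusion_matrix": cm.tolist(),
    }
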
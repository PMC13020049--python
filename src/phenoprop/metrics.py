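"""Ranking metrics: AUROC (Mann–Whitney identity), PR AUC, partial AUROC.

AUROC is computed from the rank-sum statistic with midrank tie handling —
identical to the pairwise-concordance definition (fraction of concordant
positive/negative pairs, counting ties as 1/2). PR AUC is the step-function
integral of precision over recall (average precision). Partial AUROC is
restricted to the high-specificity interval [min_specificity, 1.0] and
McClish-standardized so that chance maps to 0.5 and a perfect classifier to
1.0.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, roc_auc_score

from .exceptions import EvaluationError

__all__ = ["auroc", "pr_auc", "partial_auroc"]


def _check(y_true, scores):
    y = np.asarray(y_true).astype(bool)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise EvaluationError("y_true and scores must be equal-length 1-D arrays")
    if y.all() or not y.any():
        raise EvaluationError("need at least one positive and one negative")
    return y, s


def auroc(y_true, scores) -> float:
    """Area under the ROC curve via the Mann–Whitney rank statistic."""
    y, s = _check(y_true, scores)
    ranks = rankdata(s)  # midranks handle ties
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pr_auc(y_true, scores) -> float:
    """Area under the precision-recall curve (average precision)."""
    y, s = _check(y_true, scores)
    return float(average_precision_score(y, s))


def partial_auroc(y_true, scores, min_specificity: float = 0.95) -> float:
    """McClish-standardized partial AUROC over specificity in [min_spec, 1].

    Equivalent to restricting the false-positive rate to [0, 1−min_spec];
    0.5 = chance, 1.0 = perfect.
    """
    y, s = _check(y_true, scores)
    if not (0.0 < min_specificity < 1.0):
        raise ValueError("min_specificity must be in (0, 1)")
    return float(roc_auc_score(y, s, max_fpr=1.0 - min_specificity))
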
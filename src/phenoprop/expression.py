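"""Cell-type expression model: score genes by similarity of their expression
pattern to known disease genes.

Rows (genes) are z-scored across cell types so that only the *relative*
expression pattern matters — disease genes of interest are often lowly but
specifically expressed. A per-cell-type one-way ANOVA (known disease genes
vs all other genes) selects informative cell types, and a logistic
regression on those cell types produces a per-gene expression score, with a
held-out split for honest evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .exceptions import InputError, ModelError
from .metrics import auroc

logger = logging.getLogger(__name__)

__all__ = ["ExpressionMatrix", "ExpressionModelFit", "scale_expression",
           "select_celltypes_anova", "ExpressionGeneScorer",
           "fit_and_score_expression"]


@dataclass
class ExpressionMatrix:
    """Genes × cell-type expression values with a scaled flag."""

    data: pd.DataFrame
    scaled: bool = False

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def celltypes(self) -> list[str]:
        return list(self.data.columns)


def scale_expression(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each gene across cell types (sample SD, ddof=1).

    Zero-variance genes are dropped with a warning; scaling an already
    scaled matrix is a no-op up to numerical identity.
    """
    df = matrix.data
    if df.shape[1] < 2:
        raise InputError("need at least 2 cell types to scale")
    sd = df.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise InputError("all genes have zero variance across cell types")
    if (~keep).any():
        logger.warning("dropping %d zero-variance gene(s)", int((~keep).sum()))
    df = df.loc[keep]
    scaled = df.sub(df.mean(axis=1), axis=0).div(sd[keep], axis=0)
    return ExpressionMatrix(scaled, scaled=True)


def select_celltypes_anova(matrix: ExpressionMatrix, positive_genes,
                           alpha: float = 0.01) -> pd.DataFrame:
    """Per-cell-type one-way ANOVA of positives vs the rest.

    Returns a DataFrame (celltype, f_stat, pvalue, selected) sorted by
    p-value; ``selected`` marks p < alpha. Requires >= 2 genes per group.
    """
    if not matrix.scaled:
        matrix = scale_expression(matrix)
    pos = sorted(set(positive_genes) & set(matrix.data.index))
    neg = sorted(set(matrix.data.index) - set(pos))
    if len(pos) < 2 or len(neg) < 2:
        raise InputError("need >= 2 positive and >= 2 other genes in the matrix")
    rows = []
    X_pos = matrix.data.loc[pos]
    X_neg = matrix.data.loc[neg]
    for ct in matrix.celltypes:
        f, p = stats.f_oneway(X_pos[ct].to_numpy(), X_neg[ct].to_numpy())
        rows.append({"celltype": ct, "f_stat": float(f), "pvalue": float(p),
                     "selected": bool(p < alpha)})
    out = pd.DataFrame(rows).sort_values("pvalue", kind="mergesort").reset_index(drop=True)
    if not out["selected"].any():
        logger.warning("no cell type passes ANOVA at alpha=%g", alpha)
    return out


@dataclass
class ExpressionModelFit:
    """Fitted expression model: selected features, coefficients, metadata."""

    selected_celltypes: list[str]
    coefficients: dict[str, float]
    intercept: float
    holdout_frac: float
    rng_seed: int
    holdout_auroc: float | None = None


class ExpressionGeneScorer(BaseEstimator):
    """Logistic-regression scorer of genes against a positive gene class.

    fit(matrix, positive_genes) holds out ``holdout_frac`` of positives and
    of all other genes, selects cell types by ANOVA (p < alpha) on the
    training portion, and fits an L2-regularized logistic regression
    (lambda = ``ridge`` on the scaled features, small enough to act only as
    a separation guard). Fitted attributes: ``selected_celltypes_``,
    ``model_``, ``holdout_auroc_``, ``fit_``.
    """

    def __init__(self, alpha: float = 0.01, holdout_frac: float = 0.10,
                 ridge: float = 1e-4, rng_seed: int = 0):
        self.alpha = alpha
        self.holdout_frac = holdout_frac
        self.ridge = ridge
        self.rng_seed = rng_seed

    def fit(self, matrix: ExpressionMatrix, positive_genes) -> "ExpressionGeneScorer":
        if not matrix.scaled:
            matrix = scale_expression(matrix)
        self.matrix_ = matrix
        genes = np.array(matrix.genes)
        pos_mask = np.isin(genes, sorted(set(positive_genes)))
        if pos_mask.sum() < 5:
            raise ModelError(f"need >= 5 positive genes in matrix, have {pos_mask.sum()}")
        rng = np.random.default_rng(self.rng_seed)
        test_mask = np.zeros(len(genes), dtype=bool)
        for cls_mask in (pos_mask, ~pos_mask):
            idx = np.flatnonzero(cls_mask)
            n_test = max(1, int(round(self.holdout_frac * idx.size)))
            test_mask[rng.choice(idx, size=n_test, replace=False)] = True
        train = ~test_mask

        anova = select_celltypes_anova(
            ExpressionMatrix(matrix.data.loc[genes[train]], scaled=True),
            genes[train & pos_mask], alpha=self.alpha)
        selected = anova.loc[anova["selected"], "celltype"].tolist()
        if not selected:
            raise ModelError("no cell type passed the ANOVA filter; model unusable")
        self.selected_celltypes_ = selected
        self.anova_ = anova

        X = matrix.data[selected].to_numpy()
        y = pos_mask.astype(int)
        model = LogisticRegression(C=1.0 / self.ridge, max_iter=5000)
        model.fit(X[train], y[train])
        self.model_ = model
        scores_test = model.predict_proba(X[test_mask])[:, 1]
        self.holdout_auroc_ = float(auroc(y[test_mask], scores_test))
        self.fit_ = ExpressionModelFit(
            selected_celltypes=selected,
            coefficients=dict(zip(selected, model.coef_[0].tolist())),
            intercept=float(model.intercept_[0]),
            holdout_frac=self.holdout_frac,
            rng_seed=self.rng_seed,
            holdout_auroc=self.holdout_auroc_)
        return self

    def score_genes(self, matrix: ExpressionMatrix | None = None) -> pd.Series:
        """Per-gene predicted probability of belonging to the positive class."""
        matrix = matrix or self.matrix_
        if not matrix.scaled:
            matrix = scale_expression(matrix)
        X = matrix.data[self.selected_celltypes_].to_numpy()
        return pd.Series(self.model_.predict_proba(X)[:, 1], index=matrix.genes,
                         name="expression_score")


def fit_and_score_expression(matrix: ExpressionMatrix, positive_genes,
                             holdout_frac: float = 0.10, rng_seed: int = 0,
                             alpha: float = 0.01):
    """Convenience wrapper: fit, score all genes, report holdout AUROC.

    Returns (ExpressionModelFit, per-gene score Series, holdout AUROC).
    """
    scorer = ExpressionGeneScorer(alpha=alpha, holdout_frac=holdout_frac,
                                  rng_seed=rng_seed).fit(matrix, positive_genes)
    return scorer.fit_, scorer.score_genes(), scorer.holdout_auroc_
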
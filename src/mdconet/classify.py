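"""Logistic classification of sample condition from key-gene expression.

A ridge-stabilised logistic regression (small L2 penalty on
standardized features, so the fit stays well defined under complete
separation) is evaluated with stratified k-fold cross-validation; the
per-fold ROC/AUC and the average AUC are reported, together with a
random-gene baseline that repeats the procedure on uniformly drawn gene
panels of the same size.

AUC is computed as all-pairs concordance with half credit for ties,
which equals the trapezoidal area under the ROC curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .io import ExpressionMatrix, SampleLabels, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["ROCResult", "fit_logistic", "auc", "cross_validated_roc", "random_gene_baseline"]

RIDGE_LAMBDA = 1e-3  # L2 strength on standardized features


def fit_logistic(features: np.ndarray, labels: np.ndarray):
    """Fit a ridge-stabilised logistic model; return a probability scorer.

    ``features`` is samples x genes; ``labels`` is binary (0/1).  The
    features are standardized internally using the training statistics;
    the returned callable maps a samples x genes array to predicted
    probabilities of class 1.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValidationError(f"need exactly 2 classes, got {classes.size}")
    if min(np.sum(labels == c) for c in classes) < 2:
        raise ValidationError("each class needs at least 2 samples")
    mean = features.mean(axis=0)
    sd = features.std(axis=0)
    sd[sd == 0] = 1.0
    z = (features - mean) / sd
    model = LogisticRegression(C=1.0 / RIDGE_LAMBDA, solver="lbfgs", max_iter=5000)
    model.fit(z, labels)

    def score(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return model.predict_proba((x - mean) / sd)[:, 1]

    return score


def auc(scores, labels) -> float:
    """Area under the ROC curve via rank concordance (ties half-credit)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == np.max(labels)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve_points(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve (FPR, TPR) points from (0,0) to (1,1), thresholds descending."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == np.max(labels)
    order = np.argsort(-scores, kind="stable")
    tp = np.concatenate([[0], np.cumsum(pos[order])])
    fp = np.concatenate([[0], np.cumsum(~pos[order])])
    return fp / max(fp[-1], 1), tp / max(tp[-1], 1)


@dataclass
class ROCResult:
    """Cross-validated ROC summary."""

    fold_aucs: list[float]
    average_auc: float
    curves: list[tuple[np.ndarray, np.ndarray]]
    fold_assignments: np.ndarray
    seed: int
    genes: list[str] = field(default_factory=list)


def cross_validated_roc(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    genes,
    k_folds: int = 3,
    seed: int = 0,
) -> ROCResult:
    """Stratified k-fold cross-validated logistic ROC on a gene panel.

    For each fold the model is trained on the remaining folds and scored
    on the held-out samples; the per-fold AUC and their mean are
    reported.  Deterministic given ``seed``.
    """
    genes = list(genes)
    idx = matrix.gene_index(genes)
    mask_a, mask_b = labels.condition_masks(matrix)
    y = mask_b.astype(int)  # condition B is the positive class
    x = matrix.values[idx].T  # samples x genes
    smallest = min(int(mask_a.sum()), int(mask_b.sum()))
    if smallest < k_folds:
        raise ValidationError(
            f"smallest class has {smallest} samples < {k_folds} folds; use fewer folds"
        )
    splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_aucs: list[float] = []
    curves = []
    assignment = np.empty(matrix.n_samples, dtype=int)
    for fold, (train, test) in enumerate(splitter.split(x, y)):
        assignment[test] = fold
        scorer = fit_logistic(x[train], y[train])
        scores = scorer(x[test])
        fold_aucs.append(auc(scores, y[test]))
        curves.append(roc_curve_points(scores, y[test]))
    return ROCResult(
        fold_aucs=fold_aucs,
        average_auc=float(np.mean(fold_aucs)),
        curves=curves,
        fold_assignments=assignment,
        seed=seed,
        genes=genes,
    )


def random_gene_baseline(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    n_genes: int = 8,
    n_draws: int = 100,
    k_folds: int = 3,
    seed: int = 0,
    exclude=(),
) -> np.ndarray:
    """Average AUC distribution of randomly drawn gene panels.

    Repeats :func:`cross_validated_roc` on ``n_draws`` uniformly drawn
    panels of ``n_genes`` genes (excluding ``exclude``); returns the
    array of average AUCs.
    """
    pool = [g for g in matrix.genes if g not in set(exclude)]
    if n_genes > len(pool):
        raise ValidationError(
            f"cannot draw {n_genes} genes from a pool of {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty(n_draws)
    for i in range(n_draws):
        panel = rng.choice(pool, size=n_genes, replace=False)
        out[i] = cross_validated_roc(
            matrix, labels, [str(g) for g in panel], k_folds=k_folds, seed=seed + i + 1
        ).average_auc
    return out
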
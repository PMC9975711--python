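"""Secretory biomarker-panel construction and evaluation.

Candidate secretory genes differing between the two subtypes are screened
by t-test, reduced by L1-penalized logistic regression with the 1-SE rule
on the cross-validated misclassification error, optionally pruned by a
greedy AUC-guided backward elimination against a tuning cohort, and the
final panel is scored per sample with the bi-directional rank score
(up = genes higher in subtype 1, down = genes higher in subtype 2).
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from ._stats import bh_adjust, rowwise_ttest
from .data_model import BidirectionalSet, ExpressionMatrix, PanelModel, RocCurve
from .scoring import score_bidirectional

logger = logging.getLogger(__name__)


def screen_secretory_candidates(expr: ExpressionMatrix, labels: pd.Series,
                                secretory_list: Sequence[str],
                                padj_max: float = 0.05) -> pd.DataFrame:
    """Secretory genes differentially expressed between the two subtypes.

    Student's t-test (two-sided) on log2(x+1), restricted to the secretory
    genes present in the matrix; BH across tested genes; rows with
    padj < padj_max are returned with their direction (``up`` = higher in
    subtype 1).
    """
    sec = [g.upper() for g in secretory_list]
    genes = [g for g in sec if g in set(expr.gene_ids)]
    if not genes:
        raise ValueError("no secretory gene overlaps the expression matrix")
    labels = labels.reindex(expr.sample_ids)
    if labels.isna().any():
        raise ValueError("subtype labels missing for some samples")
    log = expr.log2p1().loc[genes]
    y = labels.to_numpy()
    a = log.loc[:, np.asarray(expr.sample_ids)[y == 1]].to_numpy()
    b = log.loc[:, np.asarray(expr.sample_ids)[y == 2]].to_numpy()
    t, p, _ = rowwise_ttest(a, b, equal_var=True)
    tab = pd.DataFrame(
        {
            "mean_subtype1": a.mean(axis=1),
            "mean_subtype2": b.mean(axis=1),
            "log2fc": a.mean(axis=1) - b.mean(axis=1),
            "t_stat": t,
            "p": p,
            "padj": bh_adjust(p),
        },
        index=genes,
    )
    tab = tab[tab["padj"] < padj_max].copy()
    tab["direction"] = np.where(tab["log2fc"] > 0, "up", "down")
    return tab


def lasso_select(feature_matrix: pd.DataFrame, labels: Sequence[int], seed: int = 0,
                 n_folds: int = 10, n_lambda: int = 100,
                 lambda_decades: float = 4.0) -> Tuple[List[str], float]:
    """L1-logistic feature selection with the 1-SE rule.

    Fits a descending lambda path (log-spaced over ``lambda_decades`` from
    the smallest lambda that zeroes every coefficient), estimates the
    misclassification error by stratified k-fold CV, picks the largest
    lambda whose CV error is within one standard error of the minimum, and
    returns the features with nonzero coefficients at that lambda.
    Features are standardized internally; zero-variance features are
    dropped with a warning.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    y01 = (y == classes[1]).astype(float)
    counts = [int((y01 == v).sum()) for v in (0, 1)]
    if min(counts) < n_folds:
        raise ValueError(f"need >= {n_folds} samples per class for {n_folds}-fold CV")

    X = feature_matrix.copy()
    sd = X.std(axis=0, ddof=0)
    dead = list(X.columns[sd == 0])
    if dead:
        logger.warning("dropping %d zero-variance feature(s): %s", len(dead), dead[:10])
        X = X.drop(columns=dead)
        sd = sd.drop(dead)
    if X.shape[1] == 0:
        raise ValueError("no informative features left")
    Z = ((X - X.mean(axis=0)) / sd).to_numpy()
    n = Z.shape[0]

    # glmnet-style path: lambda_max zeroes all coefficients of the
    # (1/n) loss + lambda * ||w||_1 objective
    lam_max = np.abs(Z.T @ (y01 - y01.mean())).max() / n
    lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max) - lambda_decades, n_lambda)

    def fit(ztr: np.ndarray, ytr: np.ndarray, lam: float) -> LogisticRegression:
        clf = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                 C=1.0 / (len(ytr) * lam), random_state=seed,
                                 max_iter=1000)
        return clf.fit(ztr, ytr)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_err = np.zeros((n_folds, n_lambda))
    for fi, (tr, te) in enumerate(skf.split(Z, y01)):
        for li, lam in enumerate(lambdas):
            clf = fit(Z[tr], y01[tr], lam)
            fold_err[fi, li] = float((clf.predict(Z[te]) != y01[te]).mean())
    cv_err = fold_err.mean(axis=0)
    cv_se = fold_err.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(cv_err))
    threshold = cv_err[i_min] + cv_se[i_min]
    i_sel = int(np.nonzero(cv_err <= threshold)[0][0])  # lambdas descend: first = largest
    lam_sel = float(lambdas[i_sel])
    clf = fit(Z, y01, lam_sel)
    selected = [c for c, w in zip(X.columns, clf.coef_.ravel()) if w != 0.0]
    return selected, lam_sel


def panel_score(expr: ExpressionMatrix, panel: PanelModel) -> pd.Series:
    """Bi-directional rank score of the panel (higher = more subtype-1-like)."""
    bset = BidirectionalSet("panel", panel.up_genes, panel.down_genes)
    return score_bidirectional(expr, bset)


def roc_auc(scores: Sequence[float], binary_labels: Sequence) -> RocCurve:
    """ROC curve and tie-corrected AUC (the rank / Mann-Whitney statistic).

    AUC is the probability that a random positive outscores a random
    negative, counting ties as 1/2.  ``binary_labels`` is boolean-like;
    truthy values are positives.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    r = rankdata(s)
    auc = (r[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    # curve: sweep thresholds over unique scores, descending
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    uniq_mask = np.r_[np.diff(s_sorted) != 0, True]
    tp = np.cumsum(y_sorted)[uniq_mask]
    fp = np.cumsum(~y_sorted)[uniq_mask]
    thresholds = np.r_[np.inf, s_sorted[uniq_mask]]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=float(auc))


def backward_eliminate(panel: PanelModel, expr_train: ExpressionMatrix,
                       labels_train: pd.Series, expr_tune: ExpressionMatrix,
                       labels_tune: pd.Series,
                       candidates: Optional[Sequence[str]] = None,
                       auc_drop_tol: float = 0.01,
                       padj_cutoff: float = 0.01) -> PanelModel:
    """Greedy AUC-guided pruning of panel genes against a tuning cohort.

    Candidates default to the panel genes whose between-subtype difference
    is *not* highly significant (BH-adjusted t-test p > ``padj_cutoff`` on
    the training cohort), tried in order of decreasing padj.  A removal is
    accepted iff the tuning AUC strictly increases while the training AUC
    drops by at most ``auc_drop_tol``; a removal that would empty either
    panel side is never accepted.
    """
    def aucs(p: PanelModel) -> Tuple[float, float]:
        tr = roc_auc(panel_score(expr_train, p).to_numpy(),
                     labels_train.reindex(expr_train.sample_ids).to_numpy() == 1).auc
        tu = roc_auc(panel_score(expr_tune, p).to_numpy(),
                     labels_tune.reindex(expr_tune.sample_ids).to_numpy() == 1).auc
        return tr, tu

    if candidates is None:
        tab = screen_secretory_candidates(expr_train, labels_train, panel.genes, padj_max=np.inf)
        tab = tab.loc[[g for g in panel.genes if g in tab.index]]
        weak = tab[tab["padj"] > padj_cutoff]
        candidates = list(weak.sort_values("padj", ascending=False).index)
    else:
        candidates = [g.upper() for g in candidates]
        unknown = set(candidates) - set(panel.genes)
        if unknown:
            raise ValueError(f"candidates not in the panel: {sorted(unknown)[:5]}")

    up, down = list(panel.up_genes), list(panel.down_genes)
    cur_train, cur_tune = aucs(panel)
    pending = list(candidates)
    improved = True
    while improved:
        improved = False
        for gene in list(pending):
            if gene in up:
                new_up, new_down = [g for g in up if g != gene], down
            elif gene in down:
                new_up, new_down = up, [g for g in down if g != gene]
            else:
                pending.remove(gene)
                continue
            if len(new_up) < 2 or len(new_down) < 2:
                continue  # a side may never be emptied (or shrink below the scoring minimum)
            trial = PanelModel(new_up, new_down, panel.lambda_selected)
            t_train, t_tune = aucs(trial)
            if t_tune > cur_tune and (cur_train - t_train) <= auc_drop_tol:
                up, down = list(new_up), list(new_down)
                cur_train, cur_tune = t_train, t_tune
                pending.remove(gene)
                improved = True
                break
    return PanelModel(up, down, panel.lambda_selected,
                      discovery_auc=cur_train, validation_auc=cur_tune)


def build_panel(expr: ExpressionMatrix, labels: pd.Series, secretory_list: Sequence[str],
                seed: int = 0, padj_max: float = 0.05, n_folds: int = 10,
                expr_tune: Optional[ExpressionMatrix] = None,
                labels_tune: Optional[pd.Series] = None,
                auc_drop_tol: float = 0.01) -> PanelModel:
    """Candidate screen -> LASSO 1-SE -> optional backward elimination."""
    cand = screen_secretory_candidates(expr, labels, secretory_list, padj_max=padj_max)
    if cand.empty:
        raise ValueError("no secretory gene passed the candidate screen")
    feats = expr.log2p1().loc[cand.index].T  # samples x genes
    y = labels.reindex(expr.sample_ids).to_numpy()
    selected, lam = lasso_select(feats, y, seed=seed, n_folds=n_folds)
    up = [g for g in selected if cand.loc[g, "direction"] == "up"]
    down = [g for g in selected if cand.loc[g, "direction"] == "down"]
    if not up or not down:
        raise ValueError("LASSO selection left an empty panel side")
    panel = PanelModel(up, down, lam)
    disc_auc = roc_auc(panel_score(expr, panel).to_numpy(), y == 1).auc
    panel.discovery_auc = disc_auc
    if expr_tune is not None and labels_tune is not None:
        panel = backward_eliminate(panel, expr, labels, expr_tune, labels_tune,
                                   auc_drop_tol=auc_drop_tol)
    return panel
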
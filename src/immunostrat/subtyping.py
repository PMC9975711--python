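"""Subtype discovery from immune-cell fraction matrices.

k-means on raw fractions (Euclidean; proportions are already commensurate),
model selection by average silhouette width, centroid assignment of new
cohorts, recursive-feature-elimination ranking of cell types, and
per-cell-type fraction comparisons between subtypes.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import silhouette_score
from sklearn.model_selection import StratifiedKFold, cross_val_score

from ._stats import bh_adjust, rowwise_ttest
from .data_model import FractionMatrix, SubtypeModel

#: Cell type used to canonicalize subtype numbering: the cluster with the
#: higher centroid fraction of resting CD4+ T cells is subtype 1 (the
#: pro-inflammatory subtype); the M2-macrophage/neutrophil-rich cluster
#: then lands on subtype 2 (pro-remodeling).
CANONICAL_CELL_TYPE = "T cells CD4 resting"


def _canonical_order(centroids: np.ndarray, cell_types: Sequence[str]) -> List[int]:
    """Order cluster indices so subtype 1 has the highest canonical fraction.

    Falls back to lexicographic centroid order when the canonical cell type
    is absent (user-supplied cell-type sets)."""
    if CANONICAL_CELL_TYPE in cell_types:
        col = list(cell_types).index(CANONICAL_CELL_TYPE)
        keys = [(-centroids[i, col], tuple(centroids[i])) for i in range(len(centroids))]
    else:
        keys = [tuple(centroids[i]) for i in range(len(centroids))]
    return sorted(range(len(centroids)), key=lambda i: keys[i])


def cluster_kmeans(fractions: FractionMatrix, k: int, seed: int = 0,
                   n_init: int = 10) -> SubtypeModel:
    """k-means subtyping of the fraction matrix (deterministic given seed).

    Cluster numbering is canonicalized (see :data:`CANONICAL_CELL_TYPE`) so
    label 1 is reproducible across seeds.
    """
    X = fractions.values
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of samples ({X.shape[0]})")
    if k < 2:
        raise ValueError("k must be >= 2")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    order = _canonical_order(km.cluster_centers_, fractions.cell_types)
    relabel = {orig: new + 1 for new, orig in enumerate(order)}
    labels = pd.Series([relabel[c] for c in km.labels_], index=fractions.sample_ids,
                       name="subtype")
    centroids = pd.DataFrame(km.cluster_centers_[order], index=range(1, k + 1),
                             columns=fractions.cell_types)
    return SubtypeModel(k=k, centroids=centroids, labels=labels, seed=seed)


def select_k_silhouette(fractions: FractionMatrix, k_range: Iterable[int],
                        seed: int = 0, n_init: int = 10) -> Tuple[int, Dict[int, float]]:
    """Choose k by maximal average silhouette width (Euclidean distance).

    Ties break toward the smallest k.
    """
    ks = sorted(set(int(k) for k in k_range))
    n = fractions.values.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not ks:
        raise ValueError("empty k range")
    if any(k < 2 for k in ks):
        raise ValueError("silhouette is undefined for k < 2")
    if any(k > n - 1 for k in ks):
        raise ValueError(f"k must be <= n_samples - 1 = {n - 1}")
    sil: Dict[int, float] = {}
    for k in ks:
        model = cluster_kmeans(fractions, k, seed=seed, n_init=n_init)
        sil[k] = float(silhouette_score(fractions.values, model.labels.to_numpy()))
    k_best = max(ks, key=lambda k: (sil[k], -k))
    return k_best, sil


def assign_by_centroid(model: SubtypeModel, fractions_new: FractionMatrix) -> pd.Series:
    """Assign samples of a new cohort to the nearest stored centroid.

    Exact distance ties resolve to the lower-numbered subtype.
    """
    if set(fractions_new.cell_types) != set(model.cell_types):
        raise ValueError("cell types of the new cohort do not match the model")
    X = fractions_new.data[model.cell_types].to_numpy()
    d = cdist(X, model.centroids.to_numpy())
    labels = d.argmin(axis=1) + 1  # argmin returns the first (lowest) index on ties
    return pd.Series(labels, index=fractions_new.sample_ids, name="subtype")


def rank_cell_types_rfe(fractions, labels: Sequence[int], seed: int = 0,
                        n_folds: int = 5) -> pd.DataFrame:
    """Rank cell types by discriminative importance via backward elimination.

    Wraps a cross-validated L2 logistic regression: at each step the feature
    whose removal least degrades mean CV accuracy is dropped; the first
    feature dropped gets the worst rank, the survivor rank 1.  Returns a
    table (index = cell type) with ``rank`` and ``cv_accuracy_without``, the
    mean CV accuracy of the model after that feature was removed.

    Accepts a :class:`FractionMatrix` or any samples x features DataFrame
    (note that on strictly compositional rows the complement of an
    informative column is itself informative, so rankings on raw fractions
    reflect joint, not marginal, importance).
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes in labels")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    X = fractions.data.copy() if isinstance(fractions, FractionMatrix) else fractions.copy()

    def cv_acc(cols: List[str]) -> float:
        clf = LogisticRegression(max_iter=2000)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return float(cross_val_score(clf, X[cols].to_numpy(), y, cv=skf).mean())

    remaining = list(X.columns)
    ranks: Dict[str, int] = {}
    acc_without: Dict[str, float] = {}
    while len(remaining) > 1:
        trial = [cv_acc([c for c in remaining if c != f]) for f in remaining]
        drop_i = int(np.argmax(trial))
        dropped = remaining.pop(drop_i)
        ranks[dropped] = len(remaining) + 1
        acc_without[dropped] = trial[drop_i]
    last = remaining[0]
    ranks[last] = 1
    acc_without[last] = cv_acc([last])
    out = pd.DataFrame({"rank": pd.Series(ranks), "cv_accuracy_without": pd.Series(acc_without)})
    return out.loc[X.columns].sort_values("rank")


def compare_fractions(fractions: FractionMatrix, labels: Sequence[int]) -> pd.DataFrame:
    """Two-sided Student's t-test per cell type between the two subtypes.

    Returns a table indexed by cell type with group means, t, p and the
    BH-adjusted p across cell types.
    """
    y = np.asarray(labels)
    groups = np.unique(y)
    if len(groups) != 2:
        raise ValueError("compare_fractions expects exactly two subtypes")
    X = fractions.values
    a = X[y == groups[0]].T  # cell types x samples
    b = X[y == groups[1]].T
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each subtype needs at least 2 samples")
    t, p, _ = rowwise_ttest(a, b, equal_var=True)
    return pd.DataFrame(
        {
            f"mean_subtype{groups[0]}": a.mean(axis=1),
            f"mean_subtype{groups[1]}": b.mean(axis=1),
            "t_stat": t,
            "p": p,
            "padj": bh_adjust(p),
        },
        index=fractions.cell_types,
    )
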
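"""LAFSAA: large-scale functional score and association analysis.

Screens a samples x gene-sets score matrix (the quantitative functional
matrix) for sets whose scores correlate with a target gene set (TGS,
typically the EMT hallmark) *within one subtype only*, validates hits in
an independent cohort, filters by over-representation of fibrosis-
responsive genes, clusters the surviving sets on their Spearman
correlation matrix, ranks cluster members by intra-cluster correlation
score (ICS), and intersects EMT-specific with fibrosis-specific hits.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata, spearmanr
from sklearn.metrics import silhouette_score

from ._stats import spearman_columns_vs_vector
from .data_model import AssociationRecord, GeneSetCollection, LafsaaResult, ScoreMatrix
from .fibrosis import ora_hypergeometric

logger = logging.getLogger(__name__)

MIN_SUBTYPE_N = 5


def _subtype_masks(labels: pd.Series) -> Dict[int, np.ndarray]:
    masks = {s: (labels.to_numpy() == s) for s in (1, 2)}
    for s, m in masks.items():
        if m.sum() < MIN_SUBTYPE_N:
            raise ValueError(f"subtype {s} has fewer than {MIN_SUBTYPE_N} samples")
    return masks


def screen_subtype_specific(scores: ScoreMatrix, tgs_scores: pd.Series,
                            subtype_labels: pd.Series,
                            alpha: float = 0.05) -> List[AssociationRecord]:
    """Flag sets significantly correlated with the TGS in exactly one subtype.

    For each set and subtype the within-subtype Spearman correlation with
    the TGS score is tested; a set is flagged for subtype s iff p < alpha
    within s and p >= alpha in the other subtype.  Zero-variance score
    columns are skipped with a warning; a column named like the TGS is
    excluded from screening.
    """
    labels = subtype_labels.reindex(scores.sample_ids)
    if labels.isna().any():
        raise ValueError("subtype labels missing for some scored samples")
    masks = _subtype_masks(labels)
    data = scores.data
    tgs_name = tgs_scores.name
    set_names = [c for c in data.columns if c != tgs_name]
    X = data[set_names].to_numpy()
    y = tgs_scores.reindex(scores.sample_ids).to_numpy()
    if np.isnan(y).any():
        raise ValueError("TGS scores missing for some scored samples")

    stats_by_subtype = {}
    for s, m in masks.items():
        rho, p = spearman_columns_vs_vector(X[m], y[m])
        stats_by_subtype[s] = (rho, p)

    records: List[AssociationRecord] = []
    for j, name in enumerate(set_names):
        if np.isnan(stats_by_subtype[1][0][j]) or np.isnan(stats_by_subtype[2][0][j]):
            logger.warning("set %s has zero-variance scores within a subtype; skipped", name)
            continue
        for s_in, s_out in ((1, 2), (2, 1)):
            rho_in, p_in = (a[j] for a in stats_by_subtype[s_in])
            rho_out, p_out = (a[j] for a in stats_by_subtype[s_out])
            if p_in < alpha and p_out >= alpha:
                records.append(AssociationRecord(
                    set_name=name, subtype=s_in,
                    rho_in=float(rho_in), p_in=float(p_in),
                    rho_out=float(rho_out), p_out=float(p_out)))
    return records


def validate_specific_sets(records: Sequence[AssociationRecord], scores_val: ScoreMatrix,
                           tgs_val: pd.Series, labels_val: pd.Series,
                           alpha: float = 0.05) -> List[AssociationRecord]:
    """Re-test each flagged set in an independent cohort, within its subtype.

    A record validates iff the validation-cohort Spearman p < alpha and the
    correlation has the same sign as in the discovery screen.
    """
    labels = labels_val.reindex(scores_val.sample_ids)
    masks = _subtype_masks(labels)
    y = tgs_val.reindex(scores_val.sample_ids).to_numpy()
    out: List[AssociationRecord] = []
    for rec in records:
        if rec.set_name not in scores_val.data.columns:
            raise ValueError(f"set {rec.set_name!r} missing from the validation score matrix")
        m = masks[rec.subtype]
        rho, p = spearmanr(scores_val.data[rec.set_name].to_numpy()[m], y[m])
        validated = bool(p < alpha and np.sign(rho) == np.sign(rec.rho_in))
        out.append(AssociationRecord(rec.set_name, rec.subtype, rec.rho_in, rec.p_in,
                                     rec.rho_out, rec.p_out, validated=validated,
                                     enrichment_p=rec.enrichment_p))
    return out


def filter_by_enrichment(records: Sequence[AssociationRecord],
                         de_genes_by_subtype: Dict[int, Sequence[str]],
                         collection: GeneSetCollection, universe: Sequence[str],
                         alpha: float = 0.05) -> List[AssociationRecord]:
    """Keep records whose set is over-represented in its subtype's DE genes.

    ``de_genes_by_subtype`` maps each subtype to its high-vs-low-fibrosis
    differential genes; a record survives iff the one-sided hypergeometric
    p of its set against those genes is < alpha.  Subtypes with an empty DE
    list lose all their records, with a warning.
    """
    ora_by_subtype: Dict[int, pd.DataFrame] = {}
    for s in (1, 2):
        de = list(de_genes_by_subtype.get(s, []))
        if not de:
            logger.warning("no differential genes for subtype %d; dropping its records", s)
            continue
        names = sorted({r.set_name for r in records if r.subtype == s})
        if names:
            ora_by_subtype[s] = ora_hypergeometric(de, collection.subset(names), universe)
    out: List[AssociationRecord] = []
    for rec in records:
        tab = ora_by_subtype.get(rec.subtype)
        if tab is None or rec.set_name not in tab.index:
            continue
        p = float(tab.loc[rec.set_name, "p"])
        if p < alpha:
            out.append(AssociationRecord(rec.set_name, rec.subtype, rec.rho_in, rec.p_in,
                                         rec.rho_out, rec.p_out, validated=rec.validated,
                                         enrichment_p=p))
    return out


def spearman_corr_matrix(scores: ScoreMatrix, set_names: Sequence[str]) -> pd.DataFrame:
    """Symmetric Spearman correlation matrix of score columns (unit diagonal)."""
    X = scores.data[list(set_names)].to_numpy()
    if np.ptp(X, axis=0).min() == 0:
        bad = [set_names[i] for i in np.nonzero(np.ptp(X, axis=0) == 0)[0][:5]]
        raise ValueError(f"zero-variance score columns: {bad}")
    R = rankdata(X, axis=0)
    C = np.corrcoef(R, rowvar=False)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=list(set_names), columns=list(set_names))


def cluster_gene_sets(scores: ScoreMatrix, set_names: Sequence[str],
                      k: Union[int, str] = "auto",
                      max_k: int = 12) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Hierarchically cluster gene sets on 1 - Spearman rho, average linkage.

    With ``k="auto"`` the cut maximizing average silhouette width over
    2..min(max_k, n_sets-1) is used (ties to the smallest k).
    """
    names = list(set_names)
    if len(names) < 2:
        raise ValueError("need at least 2 gene sets to cluster")
    corr = spearman_corr_matrix(scores, names)
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")

    def cut(kk: int) -> np.ndarray:
        return fcluster(Z, t=kk, criterion="maxclust")

    if k == "auto":
        best_k, best_sil = None, -np.inf
        for kk in range(2, min(max_k, len(names) - 1) + 1):
            lab = cut(kk)
            if len(np.unique(lab)) < 2:
                continue
            sil = silhouette_score(dist, lab, metric="precomputed")
            if sil > best_sil + 1e-12:
                best_k, best_sil = kk, sil
        if best_k is None:
            best_k = 2
        k_use = best_k
    else:
        k_use = int(k)
        if k_use < 2:
            raise ValueError("k must be >= 2 (silhouette and cluster structure undefined)")
    labels = cut(k_use)
    clusters = {name: int(c) for name, c in zip(names, labels)}
    return corr, clusters


def intra_cluster_scores(corr_matrix: pd.DataFrame, clusters: Dict[str, int],
                         include_self: bool = True) -> Dict[str, float]:
    """Intra-cluster correlation score: a set's mean Spearman correlation
    with the members of its cluster.

    The literal definition averages over all n cluster members including
    the set itself (so a singleton cluster scores 1).  ``include_self=False``
    averages over the other n-1 members instead; within a fixed cluster the
    two variants are affine transforms of each other, so rankings agree.
    """
    missing = [s for s in clusters if s not in corr_matrix.index]
    if missing:
        raise ValueError(f"sets absent from the correlation matrix: {missing[:5]}")
    members_by_cluster: Dict[int, List[str]] = {}
    for name, c in clusters.items():
        members_by_cluster.setdefault(c, []).append(name)
    ics: Dict[str, float] = {}
    for name, c in clusters.items():
        members = members_by_cluster[c]
        total = float(corr_matrix.loc[name, members].sum())
        if include_self:
            ics[name] = total / len(members)
        else:
            ics[name] = 1.0 if len(members) == 1 else (total - 1.0) / (len(members) - 1)
    return ics


def select_representatives(ics: Dict[str, float], clusters: Dict[str, int],
                           top_frac: float = 0.3) -> Dict[int, List[str]]:
    """Top-ICS representatives per cluster: the ceil(top_frac * n) highest.

    Boundary ties are all included.  Representatives are ordered by
    decreasing ICS (name as deterministic tiebreak).
    """
    missing = [s for s in clusters if s not in ics]
    if missing:
        raise ValueError(f"ICS missing for sets: {missing[:5]}")
    members_by_cluster: Dict[int, List[str]] = {}
    for name, c in clusters.items():
        members_by_cluster.setdefault(c, []).append(name)
    reps: Dict[int, List[str]] = {}
    for c, members in sorted(members_by_cluster.items()):
        ordered = sorted(members, key=lambda s: (-ics[s], s))
        m = math.ceil(top_frac * len(members))
        cutoff = ics[ordered[m - 1]]
        reps[c] = [s for s in ordered if ics[s] >= cutoff]
    return reps


def intersect_fibrosis_specific(records_emt: Sequence[AssociationRecord],
                                records_fibrosis: Sequence[AssociationRecord]
                                ) -> List[Tuple[str, int]]:
    """Sets flagged (and validated, where tested) for the same subtype in
    both the EMT screen and the fibrosis-score screen."""

    def keyed(records: Sequence[AssociationRecord]) -> Dict[Tuple[str, int], AssociationRecord]:
        return {(r.set_name, r.subtype): r for r in records
                if r.validated is None or r.validated}

    emt = keyed(records_emt)
    fib = keyed(records_fibrosis)
    return sorted(set(emt) & set(fib))


def run_lafsaa(scores: ScoreMatrix, tgs_scores: pd.Series, subtype_labels: pd.Series,
               alpha: float = 0.05,
               scores_val: Optional[ScoreMatrix] = None,
               tgs_val: Optional[pd.Series] = None,
               labels_val: Optional[pd.Series] = None,
               de_genes_by_subtype: Optional[Dict[int, Sequence[str]]] = None,
               collection: Optional[GeneSetCollection] = None,
               universe: Optional[Sequence[str]] = None,
               k: Union[int, str] = "auto",
               top_frac: float = 0.3,
               records_fibrosis: Optional[Sequence[AssociationRecord]] = None) -> LafsaaResult:
    """Full LAFSAA chain: screen, optional validation, optional enrichment
    filter, clustering, ICS and representative selection."""
    records = screen_subtype_specific(scores, tgs_scores, subtype_labels, alpha=alpha)
    if scores_val is not None:
        records = validate_specific_sets(records, scores_val, tgs_val, labels_val, alpha=alpha)
        records = [r for r in records if r.validated]
    if de_genes_by_subtype is not None and collection is not None and universe is not None:
        records = filter_by_enrichment(records, de_genes_by_subtype, collection, universe,
                                       alpha=alpha)
    result = LafsaaResult(records=records)
    names = sorted({r.set_name for r in records})
    if len(names) >= 2:
        corr, clusters = cluster_gene_sets(scores, names, k=k)
        ics = intra_cluster_scores(corr, clusters)
        result.corr_matrix = corr
        result.clusters = clusters
        result.ics = ics
        result.representatives = select_representatives(ics, clusters, top_frac=top_frac)
    if records_fibrosis is not None:
        result.fibrosis_specific = intersect_fibrosis_specific(records, records_fibrosis)
    return result
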
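"""Rank-based single-sample gene-set scoring.

Each sample is scored independently from the ranks of its expression
values, so scores are invariant to any strictly monotone per-sample
transform of expression (log, library-size scaling, ...).  For a set of
n genes in a transcriptome of N genes, the uni-directional score is the
mean rank of the set genes, rescaled so that the lowest attainable mean
rank maps to -0.5 and the highest to +0.5:

    score = (meanRank - (n+1)/2) / ((2N-n+1)/2 - (n+1)/2) - 0.5

The bi-directional score of an (up, down) gene pair adds the up score to
the score of the down genes computed on reversed ranks (N+1-rank), giving
a range of [-1, 1]; swapping up and down negates it.
"""

from __future__ import annotations

import logging
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_model import BidirectionalSet, ExpressionMatrix, GeneSetCollection, ScoreMatrix

logger = logging.getLogger(__name__)

MIN_SET_OVERLAP = 2


def _sample_ranks(expr: ExpressionMatrix) -> np.ndarray:
    """Ascending average ranks of every gene within each sample (column).

    Raises on all-constant samples, whose ranks carry no information.
    """
    vals = expr.values
    spread = vals.max(axis=0) - vals.min(axis=0)
    if (spread == 0).any():
        bad = [expr.sample_ids[i] for i in np.nonzero(spread == 0)[0][:5]]
        raise ValueError(f"all-constant expression in samples {bad}; ranks undefined")
    return rankdata(vals, axis=0)


def _present_indices(expr: ExpressionMatrix, genes: Sequence[str], label: str) -> np.ndarray:
    wanted = [g.upper() for g in genes]
    index = pd.Index(expr.gene_ids)
    locs = index.get_indexer(wanted)
    missing = [g for g, i in zip(wanted, locs) if i < 0]
    if missing:
        logger.warning("%s: %d gene(s) absent from expression matrix, dropped: %s",
                       label, len(missing), missing[:10])
    present = locs[locs >= 0]
    if len(present) < MIN_SET_OVERLAP:
        raise ValueError(
            f"{label}: only {len(present)} gene(s) present in the expression matrix; "
            f"need at least {MIN_SET_OVERLAP}"
        )
    return present


def _score_from_ranks(mean_rank: np.ndarray, n_set: int, n_genes: int) -> np.ndarray:
    low = (n_set + 1) / 2.0
    high = (2 * n_genes - n_set + 1) / 2.0
    return (mean_rank - low) / (high - low) - 0.5


def score_unidirectional(expr: ExpressionMatrix, genes: Sequence[str],
                         label: str = "gene set") -> pd.Series:
    """Per-sample uni-directional rank score of ``genes``, in [-0.5, 0.5].

    Genes absent from the matrix are dropped with a warning; at least two
    must remain.  Ties in expression receive average ranks.
    """
    idx = _present_indices(expr, genes, label)
    ranks = _sample_ranks(expr)
    mean_rank = ranks[idx, :].mean(axis=0)
    scores = _score_from_ranks(mean_rank, len(idx), expr.n_genes)
    return pd.Series(scores, index=expr.sample_ids, name=label)


def score_bidirectional(expr: ExpressionMatrix, bset: BidirectionalSet) -> pd.Series:
    """Per-sample bi-directional rank score, in [-1, 1].

    Up genes are scored on ascending ranks, down genes on reversed ranks
    (N+1-rank), and the two components are summed.
    """
    up_idx = _present_indices(expr, bset.up_genes, f"{bset.name}:up")
    down_idx = _present_indices(expr, bset.down_genes, f"{bset.name}:down")
    ranks = _sample_ranks(expr)
    n = expr.n_genes
    up = _score_from_ranks(ranks[up_idx, :].mean(axis=0), len(up_idx), n)
    down = _score_from_ranks((n + 1 - ranks[down_idx, :]).mean(axis=0), len(down_idx), n)
    return pd.Series(up + down, index=expr.sample_ids, name=bset.name)


def score_collection(expr: ExpressionMatrix, collection: GeneSetCollection) -> ScoreMatrix:
    """Score every set of a collection; the quantitative functional matrix.

    Sets overlapping the matrix by fewer than two genes are skipped with a
    warning; column order follows collection order of the retained sets.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    ranks = _sample_ranks(expr)
    index = pd.Index(expr.gene_ids)
    n = expr.n_genes
    cols = {}
    for s in collection:
        locs = index.get_indexer(s.genes)
        present = locs[locs >= 0]
        if len(present) < MIN_SET_OVERLAP:
            logger.warning("set %s overlaps expression matrix by %d gene(s); skipped",
                           s.name, len(present))
            continue
        cols[s.name] = _score_from_ranks(ranks[present, :].mean(axis=0), len(present), n)
    if not cols:
        raise ValueError("no gene set overlaps the expression matrix by >=2 genes")
    data = pd.DataFrame(cols, index=expr.sample_ids)
    return ScoreMatrix(data, mode="uni")
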
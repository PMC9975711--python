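"""Fibrosis scoring and downstream group accounting.

The fibrosis score is the uni-directional rank score of five canonical
fibrosis marker genes (POSTN, COL1A1, TIMP1, MMP2, ACTA2 — extracellular
matrix deposition, matrix-remodeling enzymes, and activated-fibroblast
actin).  Samples are split at the median score into high/low fibrosis
groups, cross-tabulated against subtypes, and compared by differential
expression; fold-change filters, feature-vector correlations and
hypergeometric over-representation round out the downstream machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, pearsonr, spearmanr

from ._stats import bh_adjust, rowwise_ttest
from .data_model import ExpressionMatrix, GeneSetCollection
from .scoring import score_unidirectional

#: Canonical fibrosis marker genes.
FIBROSIS_MARKERS = ("POSTN", "COL1A1", "TIMP1", "MMP2", "ACTA2")


def fibrosis_score(expr: ExpressionMatrix) -> pd.Series:
    """Per-sample uni-directional rank score of the 5 fibrosis markers."""
    return score_unidirectional(expr, FIBROSIS_MARKERS, label="fibrosis")


def median_split(scores: pd.Series) -> pd.Series:
    """Label samples ``high`` iff score > median, else ``low`` (strict rule).

    With an odd number of distinct scores this yields (n-1)/2 high and
    (n+1)/2 low samples; the all-tied degenerate case is all ``low``.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 samples")
    med = scores.median()
    return pd.Series(np.where(scores > med, "high", "low"), index=scores.index,
                     name="fibrosis_level")


def _round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(str(x)).quantize(Decimal("1." + "0" * ndigits), rounding=ROUND_HALF_UP))


@dataclass
class PartitionReport:
    """Subtype x fibrosis-level cross-tabulation with percent-of-total."""

    counts: pd.DataFrame  # index: subtype, columns: [high, low]
    percent_of_total: pd.DataFrame  # same shape, 2-decimal half-up percentages

    @property
    def n_samples(self) -> int:
        return int(self.counts.to_numpy().sum())


def group_partition_report(subtype_labels: Sequence[int],
                           fibrosis_labels: Sequence[str]) -> PartitionReport:
    """Cross-tabulate subtype x high/low fibrosis with percent of all samples.

    Percentages use the total sample count as denominator and half-up
    rounding to 2 decimals, so they sum to 100 up to rounding (±0.02).
    """
    sub = pd.Series(list(subtype_labels), name="subtype")
    fib = pd.Series(list(fibrosis_labels), name="fibrosis_level")
    if len(sub) != len(fib):
        raise ValueError("label vectors differ in length")
    counts = pd.crosstab(sub, fib)
    for col in ("high", "low"):
        if col not in counts.columns:
            counts[col] = 0
    counts = counts[["high", "low"]]
    total = len(sub)
    pct_exact = counts * 100.0 / total
    pct = pct_exact.apply(lambda col: col.map(_round_half_up))
    return PartitionReport(counts=counts, percent_of_total=pct)


def differential_expression(expr: ExpressionMatrix, samples_a: Sequence[str],
                            samples_b: Sequence[str]) -> pd.DataFrame:
    """Welch two-sided t-test per gene on log2(x+1), BH-adjusted across genes.

    ``log2fc`` is mean(a) - mean(b) on the log2 scale.  Genes constant
    within both groups get t = 0, p = 1 and ``constant`` = True.
    """
    log = expr.log2p1()
    a = log.loc[:, list(samples_a)].to_numpy()
    b = log.loc[:, list(samples_b)].to_numpy()
    t, p, const = rowwise_ttest(a, b, equal_var=False)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": mean_a - mean_b,
            "t_stat": t,
            "p": p,
            "padj": bh_adjust(p),
            "constant": const,
        },
        index=expr.gene_ids,
    )


def _check_universe(de_a: pd.DataFrame, de_b: pd.DataFrame) -> None:
    if set(de_a.index) != set(de_b.index):
        raise ValueError("differential-expression tables cover different gene universes")


def double_fold_filter(de_subtype1: pd.DataFrame, de_subtype2: pd.DataFrame) -> List[str]:
    """Genes whose subtype-1 log2 fold change doubles the subtype-2 one.

    Keeps genes with log2fc1 > 0 and log2fc1 >= 2 * log2fc2 (a negative
    log2fc2 passes automatically when log2fc1 is positive).
    """
    _check_universe(de_subtype1, de_subtype2)
    fc2 = de_subtype2["log2fc"].reindex(de_subtype1.index)
    keep = (de_subtype1["log2fc"] > 0) & (de_subtype1["log2fc"] >= 2 * fc2)
    return list(de_subtype1.index[keep])


def common_upregulated(de_a: pd.DataFrame, de_b: pd.DataFrame,
                       padj_max: float = 0.05) -> List[str]:
    """Genes up-regulated (log2fc > 0, padj < padj_max) in both tables."""
    _check_universe(de_a, de_b)
    b = de_b.reindex(de_a.index)
    keep = ((de_a["log2fc"] > 0) & (de_a["padj"] < padj_max)
            & (b["log2fc"] > 0) & (b["padj"] < padj_max))
    return list(de_a.index[keep])


def correlate_features_with_vector(matrix: pd.DataFrame, vector: Sequence[float],
                                   method: str = "pearson") -> pd.DataFrame:
    """Correlate each row of ``matrix`` (features x samples) with ``vector``.

    Returns r and two-sided p per feature; zero-variance features are
    flagged and reported as NaN rather than correlated.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    y = np.asarray(vector, dtype=float)
    if matrix.shape[1] != len(y):
        raise ValueError("vector length does not match the number of samples")
    corr = pearsonr if method == "pearson" else spearmanr
    rows = []
    for _, row in matrix.iterrows():
        x = row.to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((np.nan, np.nan, True))
        else:
            r, p = corr(x, y)
            rows.append((float(r), float(p), False))
    return pd.DataFrame(rows, columns=["r", "p", "zero_variance"], index=matrix.index)


def ora_hypergeometric(hit_genes: Sequence[str], collection: GeneSetCollection,
                       universe: Sequence[str]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of hits in each set.

    Sets are intersected with the universe; p is the upper tail
    P(overlap >= observed) and BH adjustment runs across sets.
    """
    uni = set(g.upper() for g in universe)
    if not uni:
        raise ValueError("empty gene universe")
    hits = set(g.upper() for g in hit_genes)
    if not hits <= uni:
        raise ValueError("hit genes must be a subset of the universe")
    M, N = len(uni), len(hits)
    rows = []
    for s in collection:
        members = set(s.genes) & uni
        k = len(members & hits)
        p = float(hypergeom.sf(k - 1, M, len(members), N)) if members else 1.0
        rows.append((s.name, len(members), k, p))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"]).set_index("set")
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out
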
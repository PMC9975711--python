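"""Core domain containers for the subtyping / scoring / panel pipeline.

All tabular containers wrap a :class:`pandas.DataFrame` and validate their
invariants on construction.  Orientation conventions follow the field's
habits: expression matrices are genes x samples, fraction and score
matrices are samples x features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

FRACTION_ROW_SUM_TOL = 1e-6
FRACTION_RENORM_TOL = 1e-3

#: The 22 leukocyte labels of the LM22 reference signature (the cell-type
#: columns produced by bulk immune deconvolution against LM22).
LM22_CELL_TYPES: tuple[str, ...] = (
    "B cells naive",
    "B cells memory",
    "Plasma cells",
    "T cells CD8",
    "T cells CD4 naive",
    "T cells CD4 resting",
    "T cells CD4 memory activated",
    "T cells follicular helper",
    "T cells regulatory (Tregs)",
    "T cells gamma delta",
    "NK cells resting",
    "NK cells activated",
    "Monocytes",
    "Macrophages M0",
    "Macrophages M1",
    "Macrophages M2",
    "Dendritic cells resting",
    "Dendritic cells activated",
    "Mast cells resting",
    "Mast cells activated",
    "Eosinophils",
    "Neutrophils",
)


def _check_unique(ids: Sequence, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values (counts, RPKM or log2 RPKM)."""

    data: pd.DataFrame
    unit_kind: str = "rpkm"

    _UNITS = ("counts", "rpkm", "log2rpkm")

    def __post_init__(self) -> None:
        if self.unit_kind not in self._UNITS:
            raise ValueError(f"unit_kind must be one of {self._UNITS}")
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("expression values must be finite")
        if self.unit_kind != "log2rpkm" and (vals < 0).any():
            raise ValueError("expression values must be nonnegative")
        self.data.index = self.data.index.astype(str).str.upper()

    @property
    def gene_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def log2p1(self) -> pd.DataFrame:
        """Expression on log2(x+1) scale (identity if already log scale)."""
        if self.unit_kind == "log2rpkm":
            return self.data.copy()
        return np.log2(self.data + 1.0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)].copy(), self.unit_kind)


@dataclass
class FractionMatrix:
    """Samples x cell-type proportions; each row lies on the simplex."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "cell types")
        vals = self.data.to_numpy()
        if (vals < -FRACTION_ROW_SUM_TOL).any() or (vals > 1 + FRACTION_ROW_SUM_TOL).any():
            raise ValueError("fractions must lie in [0, 1]")
        sums = vals.sum(axis=1)
        bad = np.abs(sums - 1.0) > FRACTION_ROW_SUM_TOL
        if bad.any():
            raise ValueError(
                f"fraction rows must sum to 1 within {FRACTION_ROW_SUM_TOL}; "
                f"offending samples: {list(self.data.index[bad][:5])}"
            )

    @classmethod
    def from_raw(cls, data: pd.DataFrame) -> "FractionMatrix":
        """Build from near-simplex rows, renormalizing sums within ±1e-3 of 1.

        Deconvolution outputs are near- but not exactly simplex; rows further
        than the tolerance from 1 are rejected rather than silently rescaled.
        """
        sums = data.to_numpy().sum(axis=1)
        bad = np.abs(sums - 1.0) > FRACTION_RENORM_TOL
        if bad.any():
            raise ValueError(
                f"fraction rows deviate from sum 1 beyond {FRACTION_RENORM_TOL}: "
                f"{list(data.index[bad][:5])}"
            )
        return cls(data.div(sums, axis=0))

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def cell_types(self) -> List[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, sample_ids: Sequence[str]) -> "FractionMatrix":
        return FractionMatrix(self.data.loc[list(sample_ids)].copy())


@dataclass
class GeneSet:
    name: str
    genes: List[str]
    description: str = ""


class GeneSetCollection:
    """Ordered collection of named gene sets (GMT-style).

    Gene symbols are case-normalized to upper case and deduplicated within
    each set, preserving first-occurrence order.
    """

    def __init__(self, sets: Optional[Sequence[GeneSet]] = None) -> None:
        self._sets: Dict[str, GeneSet] = {}
        for s in sets or []:
            self.add(s)

    def add(self, gene_set: GeneSet) -> None:
        if "\t" in gene_set.name:
            raise ValueError(f"tab character not allowed in set name: {gene_set.name!r}")
        if gene_set.name in self._sets:
            raise ValueError(f"duplicate set name: {gene_set.name}")
        genes = list(dict.fromkeys(g.strip().upper() for g in gene_set.genes if g.strip()))
        if not genes:
            raise ValueError(f"gene set {gene_set.name!r} is empty")
        self._sets[gene_set.name] = GeneSet(gene_set.name, genes, gene_set.description)

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets.values())

    @property
    def names(self) -> List[str]:
        return list(self._sets)

    def genes_of(self, name: str) -> List[str]:
        return list(self._sets[name].genes)

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection([self._sets[n] for n in names])

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return [(s.name, s.genes) for s in self] == [(s.name, s.genes) for s in other]


@dataclass
class SampleMeta:
    """Per-sample metadata record."""

    sample_id: str
    cohort: str
    status: str  # {failing, healthy}
    subtype_label: Optional[int] = None  # {1, 2}
    fibrosis_level: Optional[str] = None  # {high, low}

    _STATUS = ("failing", "healthy")
    _FIB = ("high", "low")

    def __post_init__(self) -> None:
        if self.status not in self._STATUS:
            raise ValueError(f"status must be in {self._STATUS}, got {self.status!r}")
        if self.subtype_label is not None and self.subtype_label not in (1, 2):
            raise ValueError("subtype_label must be 1 or 2")
        if self.fibrosis_level is not None and self.fibrosis_level not in self._FIB:
            raise ValueError(f"fibrosis_level must be in {self._FIB}")


def meta_to_frame(meta: Sequence[SampleMeta]) -> pd.DataFrame:
    _check_unique([m.sample_id for m in meta], "sample ids")
    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "cohort": [m.cohort for m in meta],
            "status": [m.status for m in meta],
            "subtype_label": [m.subtype_label for m in meta],
            "fibrosis_level": [m.fibrosis_level for m in meta],
        }
    ).set_index("sample_id", drop=False)


@dataclass
class ScoreMatrix:
    """Samples x gene-set signature scores ("quantitative functional matrix").

    ``mode`` is ``"uni"`` (scores in [-0.5, 0.5]) or ``"bi"`` ([-1, 1]).
    """

    data: pd.DataFrame
    mode: str = "uni"

    def __post_init__(self) -> None:
        if self.mode not in ("uni", "bi"):
            raise ValueError("mode must be 'uni' or 'bi'")
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "set names")
        vals = self.data.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("score matrix contains missing values")
        bound = 0.5 if self.mode == "uni" else 1.0
        if (np.abs(vals) > bound + 1e-9).any():
            raise ValueError(f"{self.mode}-directional scores must lie in [-{bound}, {bound}]")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def set_names(self) -> List[str]:
        return list(self.data.columns)


@dataclass
class BidirectionalSet:
    """A signed gene set: expected-up genes and expected-down genes."""

    name: str
    up_genes: List[str]
    down_genes: List[str]

    def __post_init__(self) -> None:
        self.up_genes = [g.upper() for g in self.up_genes]
        self.down_genes = [g.upper() for g in self.down_genes]
        if not self.up_genes or not self.down_genes:
            raise ValueError("up and down gene lists must both be non-empty")
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down gene lists must be disjoint")


@dataclass
class SubtypeModel:
    """Fitted k-means subtype model over immune-cell fractions."""

    k: int
    centroids: pd.DataFrame  # k x cell types, index = subtype labels 1..k
    labels: pd.Series  # per training sample, values in {1..k}
    silhouette_by_k: Dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroid count must equal k")
        if not set(self.labels.unique()) <= set(range(1, self.k + 1)):
            raise ValueError("labels must lie in 1..k")

    @property
    def cell_types(self) -> List[str]:
        return list(self.centroids.columns)


@dataclass
class PanelModel:
    """Secretory biomarker panel: genes up in subtype 1 vs up in subtype 2."""

    up_genes: List[str]
    down_genes: List[str]
    lambda_selected: float = float("nan")
    discovery_auc: Optional[float] = None
    validation_auc: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.up_genes or not self.down_genes:
            raise ValueError("panel must have non-empty up and down gene lists")
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down panel genes must be disjoint")
        for auc in (self.discovery_auc, self.validation_auc):
            if auc is not None and not (0.0 <= auc <= 1.0):
                raise ValueError("AUC must lie in [0, 1]")

    @property
    def genes(self) -> List[str]:
        return self.up_genes + self.down_genes


@dataclass
class RocCurve:
    """ROC curve and tie-corrected AUC (rank statistic)."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")
        if (np.diff(self.tpr) < -1e-12).any() or (np.diff(self.fpr) < -1e-12).any():
            raise ValueError("tpr/fpr must be nondecreasing along thresholds")


@dataclass
class AssociationRecord:
    """One gene set's subtype-specific association with the target gene set."""

    set_name: str
    subtype: int  # flagged subtype, 1 or 2
    rho_in: float
    p_in: float
    rho_out: float
    p_out: float
    validated: Optional[bool] = None
    enrichment_p: Optional[float] = None


@dataclass
class LafsaaResult:
    """Bundle of the subtype-specific gene-set association analysis."""

    records: List[AssociationRecord]
    corr_matrix: Optional[pd.DataFrame] = None
    clusters: Optional[Dict[str, int]] = None
    ics: Optional[Dict[str, float]] = None
    representatives: Optional[Dict[int, List[str]]] = None
    fibrosis_specific: Optional[List[tuple]] = None
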
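"""Synthetic heart-failure cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* two latent subtypes of immune-cell fractions drawn from shifted
  Dirichlet profiles over the 22 LM22 cell types (subtype 2 enriched in
  M2 macrophages and neutrophils; subtype 1 in resting CD4+ T cells,
  memory B cells and monocytes);
* a per-sample fibrosis latent factor loading on the five fibrosis
  marker genes and on an EMT gene set (healthy controls draw the latent
  from a lower-mean distribution);
* gene sets whose scores correlate with the EMT/fibrosis latent *only
  within one subtype* (score-level coupling via shared latents with
  subtype-gated loadings);
* secretory panel genes with a between-subtype log2 mean shift, plus
  unshifted secretory decoys;
* null genes and null gene sets.

Gene roles and gene-set membership are a deterministic function of the
configuration (a fixed structural RNG), while all sampled values depend
on ``seed`` — so cohorts generated with different seeds share planted
structure and can serve as discovery / validation pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from ._stats import spearman_columns_vs_vector
from .data_model import (
    ExpressionMatrix,
    FractionMatrix,
    GeneSet,
    GeneSetCollection,
    LM22_CELL_TYPES,
    SampleMeta,
)
from .scoring import score_unidirectional

EMT_SET_NAME = "HALLMARK_EMT"
FIBROSIS_MARKERS = ("POSTN", "COL1A1", "TIMP1", "MMP2", "ACTA2")
SUBTYPE1_UP_CELLS = ("T cells CD4 resting", "B cells memory", "Monocytes")
SUBTYPE2_UP_CELLS = ("Macrophages M2", "Neutrophils")

#: Mean healthy-control shift of the fibrosis latent (latent is N(0,1) in
#: failing samples, N(HEALTHY_LATENT_SHIFT, 1) in controls).
HEALTHY_LATENT_SHIFT = -2.0

#: Structural RNG seed: fixes gene-set membership across cohorts so that a
#: discovery and a validation cohort share planted structure.
_STRUCTURE_SEED = 20230711

#: Baseline mean immune-cell fractions (LM22 order), a plausible bulk
#: cardiac profile; sums to 1.
_BASE_MEANS: Dict[str, float] = {
    "B cells naive": 0.03,
    "B cells memory": 0.05,
    "Plasma cells": 0.04,
    "T cells CD8": 0.07,
    "T cells CD4 naive": 0.05,
    "T cells CD4 resting": 0.12,
    "T cells CD4 memory activated": 0.03,
    "T cells follicular helper": 0.03,
    "T cells regulatory (Tregs)": 0.03,
    "T cells gamma delta": 0.02,
    "NK cells resting": 0.04,
    "NK cells activated": 0.03,
    "Monocytes": 0.09,
    "Macrophages M0": 0.06,
    "Macrophages M1": 0.05,
    "Macrophages M2": 0.12,
    "Dendritic cells resting": 0.02,
    "Dendritic cells activated": 0.02,
    "Mast cells resting": 0.03,
    "Mast cells activated": 0.01,
    "Eosinophils": 0.01,
    "Neutrophils": 0.05,
}


@dataclass
class SynthConfig:
    """Generator configuration; defaults are the study conditions."""

    n_failing: int = 300
    n_healthy: int = 50
    n_genes: int = 2000
    subtype_props: Tuple[float, float] = (0.5, 0.5)
    fraction_concentration: float = 150.0
    fraction_effect: float = 0.15
    fibrosis_effect: float = 1.5
    coupling_rho: float = 0.7
    n_specific_sets_per_subtype: int = 10
    n_null_sets: int = 200
    set_size: int = 20
    n_panel_genes_per_subtype: int = 15
    panel_shift: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_failing, self.n_healthy, self.n_genes, self.set_size) < 0:
            raise ValueError("counts must be nonnegative")
        p1, p2 = self.subtype_props
        if not (0 < p1 < 1 and 0 < p2 < 1 and abs(p1 + p2 - 1) < 1e-9):
            raise ValueError("subtype_props must lie in the open simplex")
        if not (0 <= self.coupling_rho < 1):
            raise ValueError("coupling_rho must lie in [0, 1)")
        for name in ("fraction_concentration", "fraction_effect", "fibrosis_effect",
                     "panel_shift", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n_null_secretory(self) -> int:
        # twice as many unshifted secretory decoys as planted genes per subtype
        return 2 * self.n_panel_genes_per_subtype


@dataclass
class SynthTruth:
    """Planted ground truth emitted alongside a synthetic cohort."""

    subtype_labels: pd.Series  # failing samples -> {1, 2}
    fibrosis_latent: pd.Series  # all samples
    planted_specific_sets: Dict[int, List[str]]
    planted_panel_genes: Dict[int, List[str]]
    healthy: pd.Series  # all samples -> bool


@dataclass
class _GeneLayout:
    markers: List[str]
    emt: List[str]
    specific: Dict[int, List[List[str]]]  # subtype -> per-set gene lists
    panel: Dict[int, List[str]]
    null_secretory: List[str]
    null_pool: List[str]
    all_genes: List[str]


def _layout_genes(cfg: SynthConfig) -> _GeneLayout:
    markers = list(FIBROSIS_MARKERS)
    emt = [f"EMTG{i:03d}" for i in range(1, cfg.set_size + 1)]
    specific: Dict[int, List[List[str]]] = {1: [], 2: []}
    for sub in (1, 2):
        for j in range(1, cfg.n_specific_sets_per_subtype + 1):
            specific[sub].append(
                [f"SP{sub}S{j:02d}G{i:02d}" for i in range(1, cfg.set_size + 1)]
            )
    panel = {
        sub: [f"SEC{sub}_{i:02d}" for i in range(1, cfg.n_panel_genes_per_subtype + 1)]
        for sub in (1, 2)
    }
    null_sec = [f"SECN_{i:02d}" for i in range(1, cfg.n_null_secretory + 1)]
    structured = (
        markers + emt
        + [g for sub in (1, 2) for s in specific[sub] for g in s]
        + panel[1] + panel[2] + null_sec
    )
    n_null = cfg.n_genes - len(structured)
    min_null = cfg.set_size if cfg.n_null_sets > 0 else 0
    if n_null < min_null:
        raise ValueError(
            f"n_genes={cfg.n_genes} too small to host the planted structure "
            f"({len(structured)} structured genes + >= {min_null} null genes needed)"
        )
    null_pool = [f"NULL_{i:05d}" for i in range(1, n_null + 1)]
    return _GeneLayout(markers, emt, specific, panel, null_sec, null_pool,
                       structured + null_pool)


def _build_collection(cfg: SynthConfig, layout: _GeneLayout) -> GeneSetCollection:
    rng = np.random.default_rng(_STRUCTURE_SEED)
    sets: List[GeneSet] = [GeneSet(EMT_SET_NAME, layout.emt, "planted EMT driver set")]
    for sub in (1, 2):
        for j, genes in enumerate(layout.specific[sub], start=1):
            sets.append(GeneSet(f"SPECIFIC_S{sub}_{j:02d}", genes,
                                f"planted subtype-{sub}-specific set"))
    for j in range(1, cfg.n_null_sets + 1):
        genes = list(rng.choice(layout.null_pool, size=cfg.set_size, replace=False))
        sets.append(GeneSet(f"NULL_SET_{j:03d}", genes, "null set"))
    return GeneSetCollection(sets)


def _subtype_mean_vectors(cfg: SynthConfig) -> Dict[int, np.ndarray]:
    base = np.array([_BASE_MEANS[c] for c in LM22_CELL_TYPES])
    signature = set(SUBTYPE1_UP_CELLS) | set(SUBTYPE2_UP_CELLS)
    filler = np.array([c not in signature for c in LM22_CELL_TYPES])
    filler_mass = base[filler].sum()
    means = {}
    for sub, ups in ((1, SUBTYPE1_UP_CELLS), (2, SUBTYPE2_UP_CELLS)):
        m = base.copy()
        up_idx = [LM22_CELL_TYPES.index(c) for c in ups]
        m[up_idx] += cfg.fraction_effect
        added = cfg.fraction_effect * len(up_idx)
        m[filler] -= added * base[filler] / filler_mass
        if (m <= 0).any():
            raise ValueError("fraction_effect too large: a mean fraction would be <= 0")
        means[sub] = m / m.sum()
    return means


def generate_cohort(
    cfg: SynthConfig, cohort: str = "synthetic"
) -> Tuple[ExpressionMatrix, FractionMatrix, List[SampleMeta], GeneSetCollection,
           List[str], SynthTruth]:
    """Generate one cohort: expression, fractions (failing samples), metadata,
    gene-set collection, secretory gene list and planted truth.

    Deterministic given ``cfg.seed``; the planted structure (gene roles,
    set membership) depends only on the configuration.
    """
    layout = _layout_genes(cfg)
    collection = _build_collection(cfg, layout)
    rng = np.random.default_rng(cfg.seed)

    n1 = int(round(cfg.n_failing * cfg.subtype_props[0]))
    n2 = cfg.n_failing - n1
    if min(n1, n2) < 1:
        raise ValueError("each subtype needs at least one failing sample")
    failing_ids = [f"F{i:04d}" for i in range(1, cfg.n_failing + 1)]
    healthy_ids = [f"H{i:04d}" for i in range(1, cfg.n_healthy + 1)]
    sample_ids = failing_ids + healthy_ids
    subtype = np.r_[np.ones(n1, dtype=int), np.full(n2, 2, dtype=int)]

    # immune-cell fractions for the failing samples
    means = _subtype_mean_vectors(cfg)
    frac_rows = np.vstack([
        rng.dirichlet(cfg.fraction_concentration * means[1], n1),
        rng.dirichlet(cfg.fraction_concentration * means[2], n2),
    ])
    fractions = FractionMatrix(pd.DataFrame(frac_rows, index=failing_ids,
                                            columns=list(LM22_CELL_TYPES)))

    # latent factors
    n_total = cfg.n_failing + cfg.n_healthy
    fib_latent = np.r_[rng.normal(0.0, 1.0, cfg.n_failing),
                       rng.normal(HEALTHY_LATENT_SHIFT, 1.0, cfg.n_healthy)]

    gene_index = pd.Index(layout.all_genes)
    mu = rng.uniform(2.0, 8.0, len(gene_index))
    log_expr = mu[:, None] + rng.normal(0.0, cfg.noise_sd, (len(gene_index), n_total))

    def rows(genes: Sequence[str]) -> np.ndarray:
        return gene_index.get_indexer(genes)

    # fibrosis latent drives the markers and the EMT set
    log_expr[rows(layout.markers + layout.emt), :] += cfg.fibrosis_effect * fib_latent[None, :]

    # subtype-gated couplings generate the planted specific sets
    sub_all = np.r_[subtype, np.zeros(cfg.n_healthy, dtype=int)]  # 0 = healthy
    rho = cfg.coupling_rho
    for sub in (1, 2):
        gate = sub_all == sub
        for genes in layout.specific[sub]:
            z = rng.normal(0.0, 1.0, n_total)
            w = rng.normal(0.0, 1.0, n_total)
            u = np.where(gate, rho * fib_latent + math.sqrt(1.0 - rho**2) * z, w)
            log_expr[rows(genes), :] += cfg.fibrosis_effect * u[None, :]

    # secretory panel genes: mean shift within the planted subtype (failing only)
    for sub in (1, 2):
        gate = sub_all == sub
        log_expr[np.ix_(rows(layout.panel[sub]), gate)] += cfg.panel_shift

    expr = ExpressionMatrix(
        pd.DataFrame(np.exp2(log_expr), index=list(gene_index), columns=sample_ids),
        unit_kind="rpkm",
    )

    meta = [SampleMeta(sid, cohort, "failing", int(s)) for sid, s in zip(failing_ids, subtype)]
    meta += [SampleMeta(sid, cohort, "healthy") for sid in healthy_ids]

    secretory = layout.panel[1] + layout.panel[2] + layout.null_secretory
    truth = SynthTruth(
        subtype_labels=pd.Series(subtype, index=failing_ids, name="subtype"),
        fibrosis_latent=pd.Series(fib_latent, index=sample_ids, name="fibrosis_latent"),
        planted_specific_sets={
            sub: [f"SPECIFIC_S{sub}_{j:02d}"
                  for j in range(1, cfg.n_specific_sets_per_subtype + 1)]
            for sub in (1, 2)
        },
        planted_panel_genes={sub: list(layout.panel[sub]) for sub in (1, 2)},
        healthy=pd.Series([False] * cfg.n_failing + [True] * cfg.n_healthy,
                          index=sample_ids, name="healthy"),
    )
    return expr, fractions, meta, collection, secretory, truth


def planted_specificity_check(expr: ExpressionMatrix, truth: SynthTruth,
                              collection: GeneSetCollection,
                              coupling_rho: float) -> pd.DataFrame:
    """Self-test of the generator's planted subtype-specific coupling.

    For every planted set, the Spearman correlation between its
    uni-directional score and the EMT score (failing samples) should
    exceed coupling_rho/2 within its subtype and stay below it in the
    other subtype.  Report only; nothing is raised.
    """
    failing = list(truth.subtype_labels.index)
    sub_expr = expr.subset_samples(failing)
    emt = score_unidirectional(sub_expr, collection.genes_of(EMT_SET_NAME), EMT_SET_NAME)
    labels = truth.subtype_labels.to_numpy()
    threshold = coupling_rho / 2.0
    rows = []
    for sub in (1, 2):
        other = 3 - sub
        for name in truth.planted_specific_sets[sub]:
            s = score_unidirectional(sub_expr, collection.genes_of(name), name)
            rho_in, _ = spearman_columns_vs_vector(
                s.to_numpy()[labels == sub, None], emt.to_numpy()[labels == sub])
            rho_out, _ = spearman_columns_vs_vector(
                s.to_numpy()[labels == other, None], emt.to_numpy()[labels == other])
            passed = (coupling_rho == 0) or (rho_in[0] > threshold and rho_out[0] < threshold)
            rows.append((name, sub, float(rho_in[0]), float(rho_out[0]), bool(passed)))
    return pd.DataFrame(rows, columns=["set", "subtype", "rho_in", "rho_out", "passed"]
                        ).set_index("set")
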
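"""Shared fixtures: a small synthetic cohort reused across test modules and
independent oracle implementations for rank scores and AUC."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from immunostrat import ExpressionMatrix, score_collection
from immunostrat.synthetic import SynthConfig, generate_cohort


def oracle_mean_rank_score(sample_values, set_indices) -> float:
    """Exhaustive uni-directional rank score for one sample, via explicit
    tie-averaged ranks and first-principles normalization (exact
    arithmetic).  Independent of the vectorized implementation."""
    vals = list(sample_values)
    n_total = len(vals)
    ranks = []
    for i, v in enumerate(vals):
        less = sum(1 for w in vals if w < v)
        equal = sum(1 for w in vals if w == v)
        # average rank of a tie group spanning positions less+1 .. less+equal
        ranks.append(Fraction(2 * less + equal + 1, 2))
    n_set = len(set_indices)
    mean_rank = sum(ranks[i] for i in set_indices) / n_set
    lowest = Fraction(n_set + 1, 2)  # set occupies ranks 1..n
    highest = Fraction(2 * n_total - n_set + 1, 2)  # set occupies top n ranks
    return float((mean_rank - lowest) / (highest - lowest) - Fraction(1, 2))


def oracle_bidirectional_score(sample_values, up_indices, down_indices) -> float:
    """Up score plus the down score on the reversed ordering."""
    up = oracle_mean_rank_score(sample_values, up_indices)
    down = oracle_mean_rank_score([-v for v in sample_values], down_indices)
    return up + down


def oracle_pairwise_auc(scores, labels) -> float:
    """AUC by exhaustive positive/negative pair comparison (ties count 1/2)."""
    scores = list(scores)
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


SMALL_CFG = SynthConfig(
    n_failing=120,
    n_healthy=30,
    n_genes=600,
    n_specific_sets_per_subtype=3,
    n_null_sets=20,
    set_size=10,
    n_panel_genes_per_subtype=8,
    seed=7,
)


@pytest.fixture(scope="session")
def small_cohort():
    """One small synthetic cohort shared by the whole suite (read-only)."""
    return generate_cohort(SMALL_CFG)


@pytest.fixture(scope="session")
def small_cohort_pair():
    """Discovery/validation pair sharing planted structure (different seeds)."""
    cfg2 = SynthConfig(**{**SMALL_CFG.__dict__, "seed": 1007})
    return generate_cohort(SMALL_CFG), generate_cohort(cfg2)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_expression(rng, n_genes=30, n_samples=8, prefix="G") -> ExpressionMatrix:
    data = pd.DataFrame(
        rng.lognormal(2.0, 1.0, (n_genes, n_samples)),
        index=[f"{prefix}{i:03d}" for i in range(n_genes)],
        columns=[f"S{j:02d}" for j in range(n_samples)],
    )
    return ExpressionMatrix(data, unit_kind="rpkm")
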
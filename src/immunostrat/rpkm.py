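"""Reads-per-kilobase-per-million (RPKM) normalization of count matrices."""

from __future__ import annotations

from typing import Mapping, Union

import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix


def compute_rpkm(counts: ExpressionMatrix,
                 lengths: Union[Mapping[str, float], pd.Series]) -> ExpressionMatrix:
    """RPKM[g, s] = counts[g, s] * 1e9 / (length[g] * total_counts[s]).

    ``lengths`` maps gene symbols to effective transcript lengths in base
    pairs.  Library size is the column sum of the input counts.
    """
    if counts.unit_kind != "counts":
        raise ValueError("compute_rpkm expects a counts matrix")
    lengths = pd.Series(lengths)
    lengths.index = lengths.index.astype(str).str.upper()
    missing = [g for g in counts.gene_ids if g not in lengths.index]
    if missing:
        raise ValueError(f"missing gene length for: {missing[:5]}")
    lens = lengths.loc[counts.gene_ids].to_numpy(dtype=float)
    if (lens <= 0).any():
        raise ValueError("gene lengths must be positive")
    lib = counts.values.sum(axis=0)
    if (lib <= 0).any():
        bad = [counts.sample_ids[i] for i in np.nonzero(lib <= 0)[0][:5]]
        raise ValueError(f"zero library size in samples {bad}")
    rpkm = counts.values * 1e9 / (lens[:, None] * lib[None, :])
    return ExpressionMatrix(
        pd.DataFrame(rpkm, index=counts.gene_ids, columns=counts.sample_ids),
        unit_kind="rpkm",
    )
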
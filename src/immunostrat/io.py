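"""Readers and writers for the plain-text carriers: GMT gene-set files,
TSV matrices, one-symbol-per-line gene lists and sample metadata tables."""

from __future__ import annotations

import math
from pathlib import Path
from typing import List, Sequence, Union

import pandas as pd

from .data_model import (
    ExpressionMatrix,
    FractionMatrix,
    GeneSet,
    GeneSetCollection,
    SampleMeta,
    meta_to_frame,
)

PathLike = Union[str, Path]


class GmtParseError(ValueError):
    pass


def read_gmt(path: PathLike) -> GeneSetCollection:
    """Parse a GMT file (``name<TAB>description<TAB>gene...`` per line).

    Duplicate genes within a set are deduplicated (first occurrence kept);
    duplicate set names and lines with fewer than three fields are errors.
    """
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, description, *genes = fields
            try:
                collection.add(GeneSet(name, genes, description))
            except ValueError as exc:
                raise GmtParseError(f"{path}: line {lineno}: {exc}") from exc
    return collection


def write_gmt(collection: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def read_gene_list(path: PathLike) -> List[str]:
    """One gene symbol per line; blanks dropped, upper-cased, deduplicated."""
    out: List[str] = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip().upper()
            if g and g not in seen:
                seen.add(g)
                out.append(g)
    return out


def write_gene_list(genes: Sequence[str], path: PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def _read_numeric_tsv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row ids: {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate column ids: {dups[:5]}")
    bad_cols = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad_cols:
        col = bad_cols[0]
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_rows = df.index[coerced.isna() & df[col].notna()]
        row = bad_rows[0] if len(bad_rows) else df.index[coerced.isna()][0]
        raise ValueError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
    if df.isna().to_numpy().any():
        r, c = next(zip(*df.isna().to_numpy().nonzero()))
        raise ValueError(f"{path}: missing value at row {df.index[r]!r}, column {df.columns[c]!r}")
    return df


def read_matrix_tsv(
    path: PathLike, orientation: str, unit_kind: str = "rpkm"
) -> Union[ExpressionMatrix, FractionMatrix]:
    """Read a typed matrix from TSV.

    ``orientation`` is explicit, never guessed: ``"expression"`` expects rows
    = genes / columns = samples; ``"fractions"`` expects rows = samples /
    columns = cell types (rows renormalized if within 1e-3 of sum 1).
    """
    df = _read_numeric_tsv(path)
    if orientation == "expression":
        return ExpressionMatrix(df, unit_kind=unit_kind)
    if orientation == "fractions":
        return FractionMatrix.from_raw(df)
    raise ValueError("orientation must be 'expression' or 'fractions'")


def write_matrix_tsv(matrix, path: PathLike, float_format: str = "%.10g") -> None:
    matrix.data.to_csv(path, sep="\t", float_format=float_format)


_META_COLS = ["sample_id", "cohort", "status", "subtype_label", "fibrosis_level"]


def read_meta_tsv(path: PathLike) -> List[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in ("sample_id", "cohort", "status") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    out = []
    for _, row in df.iterrows():
        sub = row.get("subtype_label")
        sub = None if sub is None or (isinstance(sub, float) and math.isnan(sub)) else int(sub)
        fib = row.get("fibrosis_level")
        fib = None if fib is None or (isinstance(fib, float) and math.isnan(fib)) else str(fib)
        out.append(SampleMeta(str(row["sample_id"]), str(row["cohort"]), str(row["status"]), sub, fib))
    ids = [m.sample_id for m in out]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sample ids")
    return out


def write_meta_tsv(meta: Sequence[SampleMeta], path: PathLike) -> None:
    meta_to_frame(meta)[_META_COLS].to_csv(path, sep="\t", index=False)
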
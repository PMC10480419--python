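"""Tab-delimited readers and writers for expression matrices, gene lengths,
sample metadata, purity tables and GMT gene-set files.

All tables are TAB-delimited.  Expression files have one header row of sample
IDs and gene IDs in the first column (genes x samples orientation).
"""
from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SampleMetadata,
    Unit,
    strip_version,
)

__all__ = [
    "ParseError",
    "read_expression",
    "write_expression",
    "read_gene_lengths",
    "write_gene_lengths",
    "read_metadata",
    "write_metadata",
    "read_purity_table",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
]


class ParseError(ValueError):
    """A malformed input file; the message names the offending location."""


def read_expression(
    path: str | os.PathLike,
    unit: str | Unit,
    lengths_path: str | os.PathLike | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples TSV into a validated :class:`ExpressionMatrix`.

    Non-numeric cells raise :class:`ParseError` naming the gene and sample;
    duplicate gene IDs (after version-stripping) are an error, never merged.
    When ``unit='counts'`` a two-column lengths file (gene_id, length_bp) is
    required and every gene must have a length.
    """
    unit = Unit(unit)
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False, na_values=[]
    )
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        mask = numeric.isna().to_numpy()
        i, j = np.argwhere(mask)[0]
        raise ParseError(
            f"{path}: non-numeric value {raw.iat[i, j]!r} at gene "
            f"{raw.index[i]!r} (row {i + 2}), sample {raw.columns[j]!r} "
            f"(column {j + 2})"
        )
    lengths = None
    if lengths_path is not None:
        lengths = read_gene_lengths(lengths_path)
        stripped_lengths = {strip_version(str(g)): v for g, v in lengths.items()}
        missing = [
            g for g in numeric.index if strip_version(str(g)) not in stripped_lengths
        ]
        if missing:
            raise ParseError(
                f"{lengths_path}: missing gene length for "
                + ", ".join(map(str, missing[:10]))
            )
        lengths = pd.Series(
            [stripped_lengths[strip_version(str(g))] for g in numeric.index],
            index=numeric.index,
            name="length_bp",
        )
    elif unit == Unit.counts:
        raise ValueError("unit=counts requires lengths_path")
    return ExpressionMatrix(numeric.astype(float), unit, lengths)


def write_expression(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_gene_lengths(path: str | os.PathLike) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ParseError(f"{path}: lengths file needs 2 columns (gene_id, length_bp)")
    lengths = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if lengths.isna().any():
        i = int(lengths.index[lengths.isna()][0])
        raise ParseError(f"{path}: non-numeric length at line {i + 2}")
    s = pd.Series(lengths.to_numpy(dtype=float), index=df.iloc[:, 0], name="length_bp")
    if (s <= 0).any():
        raise ParseError(f"{path}: gene lengths must be positive")
    return s


def write_gene_lengths(lengths: pd.Series, path: str | os.PathLike) -> None:
    df = lengths.rename("length_bp").to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_metadata(path: str | os.PathLike) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | os.PathLike) -> None:
    meta.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_purity_table(path: str | os.PathLike) -> pd.Series:
    """Two-column TSV (sample_id, purity) -> Series indexed by sample ID."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ParseError(f"{path}: purity file needs 2 columns (sample_id, purity)")
    purity = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    s = pd.Series(purity.to_numpy(dtype=float), index=df.iloc[:, 0], name="purity")
    if ((s < 0) | (s > 1)).any():
        raise ParseError(f"{path}: purity values must lie in [0, 1]")
    return s


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB member TAB member ...``.

    Lines with fewer than three fields (i.e. no members) raise
    :class:`ParseError` with the line number.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected name, description and at "
                    f"least one member ({len(fields)} fields found)"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"{path}: line {lineno}: gene set {name!r} is empty")
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = GeneSet(name, description, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """One gene ID per line (blank lines ignored), version-stripped."""
    with open(path) as fh:
        return [strip_version(line.strip()) for line in fh if line.strip()]


def write_gene_list(genes, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
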
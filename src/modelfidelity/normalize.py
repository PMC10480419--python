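"""Expression normalization: counts -> TPM, TPM -> log2(TPM+1), and
cross-cohort gene-space harmonization."""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, Unit, strip_version

__all__ = ["counts_to_tpm", "log_transform", "harmonize"]

logger = logging.getLogger(__name__)


def counts_to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert raw counts to transcripts per million.

    Per sample: each gene's count is divided by its length in kilobases to
    give a read rate, and rates are scaled to sum to one million.  All-zero
    samples yield all-zero columns (with a logged warning) rather than NaNs so
    degraded samples can be excluded downstream instead of crashing ingestion.
    """
    if matrix.unit != Unit.counts:
        raise ValueError(f"counts_to_tpm requires unit=counts, got {matrix.unit.value}")
    lengths_kb = matrix.gene_lengths.to_numpy(dtype=float) / 1e3
    rates = matrix.values.to_numpy(dtype=float) / lengths_kb[:, None]
    colsums = rates.sum(axis=0)
    zero_cols = colsums == 0
    if zero_cols.any():
        bad = list(matrix.sample_ids[zero_cols])
        logger.warning("all-zero sample columns in TPM conversion: %s", bad[:10])
        colsums = np.where(zero_cols, 1.0, colsums)
    tpm = rates / colsums * 1e6
    out = pd.DataFrame(tpm, index=matrix.gene_ids, columns=matrix.sample_ids)
    return ExpressionMatrix(out, Unit.tpm, matrix.gene_lengths)


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(TPM + 1); monotone and zero-preserving."""
    if matrix.unit != Unit.tpm:
        raise ValueError(f"log_transform requires unit=tpm, got {matrix.unit.value}")
    out = pd.DataFrame(
        np.log2(matrix.values.to_numpy(dtype=float) + 1.0),
        index=matrix.gene_ids,
        columns=matrix.sample_ids,
    )
    return ExpressionMatrix(out, Unit.log2tpm, matrix.gene_lengths)


def harmonize(matrices: Sequence[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict all matrices to their common gene space.

    Gene IDs are matched after stripping Ensembl version suffixes; each output
    carries the shared genes in the same (first-matrix) order.  The number of
    genes dropped per input is logged.  An empty intersection is an error.
    """
    if len(matrices) < 2:
        raise ValueError("harmonize requires at least 2 matrices")
    stripped = [m.stripped_index() for m in matrices]
    common = stripped[0]
    for s in stripped[1:]:
        common = common.intersection(s)
    if len(common) == 0:
        raise ValueError("harmonize: no genes shared by all matrices")
    # keep the gene order of the first matrix
    ordered = [g for g in stripped[0] if g in set(common)]
    out = []
    for m, s in zip(matrices, stripped):
        dropped = len(s) - len(ordered)
        if dropped:
            logger.info("harmonize: dropping %d genes from one input", dropped)
        out.append(m.restrict_genes(ordered))
    return out
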
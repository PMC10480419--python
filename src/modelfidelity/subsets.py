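"""Gene subset construction: top-k most-variable genes, tumor-purity-correlated
genes, and tissue-specific high/low sets.

Variance ranking is computed on log2(TPM+1): raw-TPM variance is dominated by
a handful of extreme genes, and the log scale matches standard most-variable-
gene practice.  Purity-correlated genes are detected per tumor cohort by
gene-wise Spearman correlation against the purity column, with BH (or
Bonferroni) adjustment within each cohort; the exported subset is the union
of flagged genes across cohorts.  Tissue-specific sets score each gene's
per-tissue mean against the spread of the remaining tissues' means.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._stats import rowwise_spearman_vs_vector
from .containers import (
    DiseaseState,
    ExpressionMatrix,
    GeneSetCollection,
    GeneSubset,
    ModelType,
    SampleMetadata,
    Unit,
)

__all__ = [
    "top_variable_genes",
    "purity_correlated_genes",
    "PurityGeneResult",
    "exclude_genes",
    "tissue_specific_sets",
]

logger = logging.getLogger(__name__)

_ADJUST_METHODS = {"bh": "fdr_bh", "bonferroni": "bonferroni"}


def top_variable_genes(
    matrix: ExpressionMatrix,
    k: int,
    sample_ids: Sequence[str] | None = None,
    name: str | None = None,
    reference_cohort: str = "",
    variance_scale: str = "log",
) -> GeneSubset:
    """The k genes with highest cross-sample variance in a reference cohort.

    Variance is the per-gene sample variance over the selected samples (all
    samples if ``sample_ids`` is None; at least 3 required).  Genes are sorted
    by variance descending with ties broken by gene ID ascending, making the
    subset deterministic across platforms.  ``variance_scale='log'`` expects a
    log2 TPM matrix (default practice); ``'tpm'`` accepts a TPM matrix.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > matrix.n_genes:
        raise ValueError(f"k={k} exceeds gene count {matrix.n_genes}")
    expected_unit = Unit.log2tpm if variance_scale == "log" else Unit.tpm
    if variance_scale not in ("log", "tpm"):
        raise ValueError(f"unknown variance_scale {variance_scale!r}")
    if matrix.unit != expected_unit:
        raise ValueError(
            f"variance_scale={variance_scale!r} requires unit={expected_unit.value}, "
            f"got {matrix.unit.value}"
        )
    vals = matrix.values if sample_ids is None else matrix.values.loc[:, list(sample_ids)]
    if vals.shape[1] < 3:
        raise ValueError(f"variance ranking needs >= 3 samples, got {vals.shape[1]}")
    var = vals.var(axis=1, ddof=1)
    order = pd.DataFrame({"var": var, "gene": matrix.stripped_index()}, index=matrix.gene_ids)
    order = order.sort_values(by=["var", "gene"], ascending=[False, True], kind="mergesort")
    genes = list(order["gene"].iloc[:k])
    return GeneSubset(
        name or f"variance_top{k}",
        genes,
        provenance="variance_topk",
        k=k,
        reference_cohort=reference_cohort,
    )


@dataclasses.dataclass
class PurityGeneResult:
    """Per-cohort purity-correlation scan plus the cross-cohort union subset.

    ``per_cohort`` maps a cohort label to a DataFrame with columns
    (gene_id, rho, p, p_adj, flagged); a gene is flagged when its adjusted p
    is below alpha *and* |rho| >= min_abs_rho.  Genes constant within a cohort
    have undefined rho (NaN) and are never flagged.
    """

    per_cohort: dict[str, pd.DataFrame]
    union: GeneSubset
    alpha: float
    adjust: str
    min_abs_rho: float


def purity_correlated_genes(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    alpha: float = 0.05,
    adjust: str = "bh",
    min_abs_rho: float = 0.3,
    per_cohort: str = "tissue_group",
    min_samples: int = 10,
) -> PurityGeneResult:
    """Detect genes whose tumor expression tracks tumor purity.

    Within each tumor cohort (default grouping: tissue_group) with at least
    ``min_samples`` purity-annotated samples, the gene-wise Spearman rho
    against purity is computed with a two-sided t-approximation p-value and
    adjusted within the cohort.  Constant purity in a cohort is an error.
    """
    if matrix.unit != Unit.tpm:
        raise ValueError("purity_correlated_genes expects a TPM matrix")
    if adjust not in _ADJUST_METHODS:
        raise ValueError(f"unknown adjustment {adjust!r}; use 'bh' or 'bonferroni'")
    tumors = meta.select(
        disease_state=DiseaseState.tumor.value, model_type=ModelType.tissue.value
    )
    tumors = tumors[tumors["sample_id"].isin(set(matrix.sample_ids))]
    tumors = tumors[tumors["purity"].notna()]
    if tumors.empty:
        raise ValueError("no tumor samples with purity annotations")
    results: dict[str, pd.DataFrame] = {}
    flagged_union: list[str] = []
    stripped = matrix.stripped_index()
    for cohort, grp in tumors.groupby(per_cohort, sort=True):
        if len(grp) < min_samples:
            logger.warning(
                "cohort %s skipped: %d purity-annotated tumors (< %d)",
                cohort, len(grp), min_samples,
            )
            continue
        purity = grp["purity"].to_numpy(dtype=float)
        if np.all(purity == purity[0]):
            raise ValueError(f"cohort {cohort!r}: purity is constant")
        x = matrix.values.loc[:, list(grp["sample_id"])].to_numpy(dtype=float)
        constant = np.all(x == x[:, :1], axis=1)
        rho, p = rowwise_spearman_vs_vector(x, purity)
        rho[constant] = np.nan
        p[constant] = np.nan
        p_adj = np.full_like(p, np.nan)
        ok = ~np.isnan(p)
        if ok.any():
            p_adj[ok] = multipletests(p[ok], method=_ADJUST_METHODS[adjust])[1]
        flagged = ok & (p_adj < alpha) & (np.abs(rho) >= min_abs_rho)
        df = pd.DataFrame(
            {
                "gene_id": stripped,
                "rho": rho,
                "p": p,
                "p_adj": p_adj,
                "flagged": flagged,
            }
        )
        results[str(cohort)] = df
        flagged_union.extend(df.loc[df["flagged"], "gene_id"])
    if not results:
        raise ValueError(
            f"no cohort had >= {min_samples} purity-annotated tumor samples"
        )
    union_genes = sorted(set(flagged_union))
    union = GeneSubset(
        "purity_correlated_union",
        union_genes,
        provenance="purity_correlated",
        reference_cohort=",".join(sorted(results)),
    )
    return PurityGeneResult(results, union, alpha, adjust, min_abs_rho)


def exclude_genes(
    subset: GeneSubset | Sequence[str], excl: GeneSubset | Sequence[str], name: str | None = None
) -> GeneSubset:
    """Set difference preserving the order of ``subset``; provenance records
    both parents.  The result may be empty (downstream correlation operations
    reject empty subsets)."""
    base_genes = list(subset.gene_ids) if isinstance(subset, GeneSubset) else list(subset)
    base_name = subset.name if isinstance(subset, GeneSubset) else "custom"
    excl_genes = set(excl.gene_ids) if isinstance(excl, GeneSubset) else set(excl)
    excl_name = excl.name if isinstance(excl, GeneSubset) else "custom"
    kept = [g for g in base_genes if g not in excl_genes]
    return GeneSubset(
        name or f"{base_name}_minus_{excl_name}",
        kept,
        provenance="difference",
        reference_cohort=f"{base_name} \\ {excl_name}",
    )


def tissue_specific_sets(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    z_threshold: float = 3.0,
) -> GeneSetCollection:
    """Call tissue-specific high/low gene sets from non-diseased tissues.

    For each tissue t and gene g, the score is
    ``z = (mean_t - mean of the other tissues' means) / s.d. of the other
    tissues' per-tissue means``; genes with z >= z_threshold join
    ``<t>_high`` and z <= -z_threshold join ``<t>_low``.  Empty sets are
    dropped with a warning.  The score needs several reference tissues to be
    stable (with only two "other" tissues the denominator is an s.d. over two
    values and the null distribution is extremely heavy-tailed).
    """
    if matrix.unit != Unit.log2tpm:
        raise ValueError("tissue_specific_sets expects a log2 TPM matrix")
    normals = meta.select(
        disease_state=DiseaseState.non_diseased.value, model_type=ModelType.tissue.value
    )
    normals = normals[normals["sample_id"].isin(set(matrix.sample_ids))]
    tissues = sorted(normals["tissue_group"].unique())
    if len(tissues) < 2:
        raise ValueError("tissue_specific_sets needs >= 2 tissue groups")
    means = np.column_stack(
        [
            matrix.values.loc[:, list(normals.loc[normals["tissue_group"] == t, "sample_id"])]
            .mean(axis=1)
            .to_numpy()
            for t in tissues
        ]
    )  # genes x tissues
    stripped = matrix.stripped_index()
    sets: dict[str, list[str]] = {}
    for ti, t in enumerate(tissues):
        others = np.delete(means, ti, axis=1)
        center = others.mean(axis=1)
        spread = others.std(axis=1, ddof=1) if others.shape[1] > 1 else np.full(len(means), np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (means[:, ti] - center) / spread
        z = np.where(np.isfinite(z), z, 0.0)
        high = [g for g, zz in zip(stripped, z) if zz >= z_threshold]
        low = [g for g, zz in zip(stripped, z) if zz <= -z_threshold]
        for suffix, genes in (("high", high), ("low", low)):
            name = f"{t}_{suffix}"
            if genes:
                sets[name] = genes
            else:
                logger.warning("tissue-specific set %s is empty; dropped", name)
    return GeneSetCollection.from_dict(
        sets, descriptions={n: f"tissue-specific ({n.rsplit('_', 1)[1]}) z>={z_threshold}" for n in sets}
    )
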
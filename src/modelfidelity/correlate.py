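"""Model-to-tissue Spearman correlation engine.

For every preclinical model sample (cell line or PDX) and every tissue group
(a parent tissue x disease-state cohort), the engine computes the pairwise
Spearman correlation of the model's expression profile against each tissue
sample over a chosen gene subset and records the *median* of those pairwise
correlations (``rho_median``).  The matched-origin specificity statistic is
the percentage of models whose highest-ranked group, among all tumor and
non-diseased candidates, is the tumor group of their own tissue of origin.

Correlations are computed on TPM.  Spearman's rho is invariant under strictly
increasing transforms, so correlating on TPM and on log2(TPM+1) are the same
operation; each sample is rank-transformed once per gene subset and the rho
matrix is obtained as a product of standardized rank matrices.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import spearman, spearman_matrix  # noqa: F401  (spearman re-exported)
from .containers import (
    DiseaseState,
    ExpressionMatrix,
    GeneSubset,
    ModelType,
    SampleMetadata,
    Unit,
    strip_version,
)

__all__ = [
    "spearman",
    "model_to_tissue",
    "specificity",
    "SpecificitySummary",
    "pca_qc",
    "CORRELATION_COLUMNS",
]

logger = logging.getLogger(__name__)

CORRELATION_COLUMNS = [
    "model_sample_id",
    "tissue_group",
    "disease_state",
    "gene_subset",
    "rho_median",
    "n_tissue_samples",
    "n_genes_used",
]


def _resolve_subset(
    matrix: ExpressionMatrix, subset: GeneSubset | Sequence[str] | None
) -> tuple[str, list[str]]:
    if subset is None:
        return "full_set", list(matrix.gene_ids)
    if isinstance(subset, GeneSubset):
        name, genes = subset.name, list(subset.gene_ids)
    else:
        name, genes = "custom", [strip_version(g) for g in subset]
    present = set(matrix.stripped_index())
    kept = [g for g in genes if strip_version(g) in present]
    if len(kept) < 3:
        raise ValueError(
            f"gene subset {name!r} shares only {len(kept)} genes with the "
            "matrix (need >= 3)"
        )
    return name, kept


def model_to_tissue(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    subset: GeneSubset | Sequence[str] | None = None,
    model_types: Sequence[str] = (ModelType.cell_line.value, ModelType.pdx.value),
    profile: str = "per_sample",
    min_mean_tpm: float | None = None,
) -> pd.DataFrame:
    """Correlate every model sample against every tissue group.

    Parameters
    ----------
    matrix
        TPM expression matrix containing both model and tissue samples.
    meta
        Sample metadata; tissue groups are the (tissue_group, disease_state)
        cohorts of non-excluded ``model_type='tissue'`` samples.
    subset
        Gene subset to correlate over (None = all genes).
    profile
        ``'per_sample'`` (default): pairwise rho against each tissue sample,
        then the median.  ``'median'``: rho against the median tissue profile.
    min_mean_tpm
        Optional expression floor: drop subset genes whose mean TPM across
        the used samples falls below this value.

    Returns a long-format DataFrame with :data:`CORRELATION_COLUMNS`, ordered
    by (model sample ID, tissue group, disease state).
    """
    if matrix.unit != Unit.tpm:
        raise ValueError("model_to_tissue expects a TPM matrix")
    if profile not in ("per_sample", "median"):
        raise ValueError(f"unknown profile mode {profile!r}")
    meta.validate_against(matrix)
    subset_name, genes = _resolve_subset(matrix, subset)
    sub = matrix.restrict_genes(genes)

    models = meta.select(model_type=list(model_types))
    models = models[models["sample_id"].isin(set(matrix.sample_ids))]
    if models.empty:
        raise ValueError("no model samples selected")
    tissues = meta.select(model_type=ModelType.tissue.value)
    tissues = tissues[tissues["sample_id"].isin(set(matrix.sample_ids))]
    if tissues.empty:
        raise ValueError("no tissue samples available")

    model_ids = sorted(models["sample_id"])
    tissue_ids = sorted(tissues["sample_id"])
    vals = sub.values
    a = vals.loc[:, model_ids].to_numpy(dtype=float)
    b = vals.loc[:, tissue_ids].to_numpy(dtype=float)
    if min_mean_tpm is not None:
        keep = np.concatenate([a, b], axis=1).mean(axis=1) >= min_mean_tpm
        if keep.sum() < 3:
            raise ValueError("min_mean_tpm filter leaves fewer than 3 genes")
        a, b = a[keep], b[keep]
    n_genes_used = a.shape[0]

    groups = (
        tissues.groupby(["tissue_group", "disease_state"], sort=True)["sample_id"]
        .apply(sorted)
        .to_dict()
    )
    tissue_pos = {s: i for i, s in enumerate(tissue_ids)}

    if profile == "median":
        prof_cols = []
        group_keys = sorted(groups)
        for key in group_keys:
            idx = [tissue_pos[s] for s in groups[key]]
            prof_cols.append(np.median(b[:, idx], axis=1))
        rho = spearman_matrix(a, np.column_stack(prof_cols))
        records = []
        for mi, mid in enumerate(model_ids):
            for gi, (tg, ds) in enumerate(group_keys):
                records.append(
                    (mid, tg, ds, subset_name, float(rho[mi, gi]), len(groups[(tg, ds)]), n_genes_used)
                )
    else:
        rho = spearman_matrix(a, b)
        records = []
        for mi, mid in enumerate(model_ids):
            for (tg, ds), members in sorted(groups.items()):
                idx = [tissue_pos[s] for s in members]
                rho_median = float(np.median(rho[mi, idx]))
                records.append(
                    (mid, tg, ds, subset_name, rho_median, len(members), n_genes_used)
                )
    return pd.DataFrame(records, columns=CORRELATION_COLUMNS)


@dataclasses.dataclass
class SpecificitySummary:
    """Matched-origin rank specificity of a set of model samples.

    ``percent_best_match`` is 100 x (number of model samples whose top-ranked
    candidate group is the tumor group of their own tissue of origin) /
    (number of model samples).  Ranks are dense and 1-based; a matched group
    tied with others counts as best only if its rho is >= all others *and* it
    comes first under group-ID-ascending tie-break (ties are recorded).
    """

    gene_subset: str
    percent_best_match: float
    per_model: pd.DataFrame
    percent_by_model_type: dict[str, float]
    group_medians: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "gene_subset": self.gene_subset,
            "percent_best_match": self.percent_best_match,
            "percent_by_model_type": self.percent_by_model_type,
            "n_models": int(len(self.per_model)),
        }


def specificity(records: pd.DataFrame, meta: SampleMetadata) -> SpecificitySummary:
    """Rank candidate groups per model sample and score matched-origin hits.

    ``records`` is the long-format output of :func:`model_to_tissue` for a
    single gene subset; every model sample must have a record for every
    candidate (tissue group x disease state) pair.
    """
    subsets = records["gene_subset"].unique()
    if len(subsets) != 1:
        raise ValueError(f"specificity expects a single gene subset, got {list(subsets)}")
    gene_subset = str(subsets[0])

    candidate_groups = sorted(
        set(zip(records["tissue_group"], records["disease_state"]))
    )
    per_model_rows = []
    tied_any = []
    for mid, df in records.groupby("model_sample_id", sort=True):
        have = set(zip(df["tissue_group"], df["disease_state"]))
        missing = [g for g in candidate_groups if g not in have]
        if missing:
            raise ValueError(f"model {mid!r} missing records for groups: {missing}")
        row = meta.row(mid)
        matched_key = (row["tissue_group"], DiseaseState.tumor.value)
        # sort by rho descending, tie-break group key ascending
        df = df.assign(_key=list(zip(df["tissue_group"], df["disease_state"])))
        df = df.sort_values(
            by=["rho_median", "_key"], ascending=[False, True], kind="mergesort"
        )
        rhos = df["rho_median"].to_numpy()
        keys = list(df["_key"])
        # dense 1-based ranks
        uniq = np.unique(-rhos)
        dense = {(-u): r + 1 for r, u in enumerate(uniq)}
        if matched_key not in keys:
            raise ValueError(
                f"model {mid!r}: no record for its matched tumor group {matched_key}"
            )
        matched_rho = float(
            df.loc[df["_key"] == matched_key, "rho_median"].iloc[0]
        )
        matched_rank = dense[matched_rho]
        top_rho = float(rhos[0])
        tied_top = int(np.sum(rhos == top_rho)) > 1
        best_is_matched = keys[0] == matched_key
        if tied_top and best_is_matched:
            logger.info(
                "model %s: matched group tied at the top; counted best by "
                "ID-ascending tie-break", mid
            )
        per_model_rows.append(
            {
                "model_sample_id": mid,
                "model_type": row["model_type"],
                "origin_tissue": row["tissue_group"],
                "best_tissue_group": keys[0][0],
                "best_disease_state": keys[0][1],
                "best_rho": top_rho,
                "matched_rho": matched_rho,
                "matched_rank": matched_rank,
                "best_is_matched": best_is_matched,
                "tied_top": tied_top,
            }
        )
        tied_any.append(tied_top)
    per_model = pd.DataFrame(per_model_rows)
    pct = float(100.0 * per_model["best_is_matched"].mean())
    by_type = {
        str(mt): float(100.0 * grp["best_is_matched"].mean())
        for mt, grp in per_model.groupby("model_type")
    }
    merged = records.merge(
        meta.table[["sample_id", "tissue_group"]].rename(
            columns={"sample_id": "model_sample_id", "tissue_group": "origin_tissue"}
        ),
        on="model_sample_id",
    )
    group_medians = (
        merged.groupby(["origin_tissue", "tissue_group", "disease_state"])["rho_median"]
        .median()
        .reset_index()
        .rename(columns={"rho_median": "median_rho"})
    )
    return SpecificitySummary(gene_subset, pct, per_model, by_type, group_medians)


def pca_qc(
    matrix: ExpressionMatrix, meta: SampleMetadata | None = None, n_components: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered (not scaled) PCA of samples over genes, for QC plots.

    Returns (scores, explained_variance_fractions).  The sign of each
    component is fixed so its largest-magnitude gene loading is positive.
    """
    from sklearn.decomposition import PCA

    if matrix.unit != Unit.log2tpm:
        raise ValueError("pca_qc expects a log2 TPM matrix")
    n_samples = matrix.n_samples
    if n_samples < 3:
        raise ValueError("pca_qc requires at least 3 samples")
    max_comp = min(matrix.n_genes, n_samples - 1)
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(genes, samples-1)={max_comp}"
        )
    x = matrix.values.to_numpy(dtype=float).T  # samples x genes
    if np.allclose(x.var(axis=0), 0):
        raise ValueError("zero-variance data: PCA undefined")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    # sign convention: largest-|loading| positive per component
    for k in range(n_components):
        lead = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, lead] < 0:
            scores[:, k] *= -1.0
    cols = [f"PC{k + 1}" for k in range(n_components)]
    score_df = pd.DataFrame(scores, index=matrix.sample_ids, columns=cols)
    if meta is not None:
        meta_idx = meta.table.set_index("sample_id")
        for col in ("tissue_group", "disease_state", "model_type", "source"):
            score_df[col] = meta_idx[col].reindex(score_df.index)
    return score_df, pca.explained_variance_ratio_
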
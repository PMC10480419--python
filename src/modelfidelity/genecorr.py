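"""Per-gene correlation classes between a model group and a tissue group, and
hypergeometric over-representation analysis of those classes.

The two groups are unpaired sample sets, so a per-gene correlation needs an
explicit pairing rule.  The rule used here is quantile pairing: each gene's
values are sorted within the model group and within the tissue group, both
empirical distributions are evaluated at n = min(n_model, n_tissue) equally
spaced quantile points (linear / type-7 interpolation), and Spearman's rho
with its t-approximation p-value is computed on the paired quantiles.  This
is deterministic, invariant to sample order, and gives rho = 1 for identical
distributions.  Genes constant in either group have undefined rho.

Because both quantile vectors are nondecreasing by construction, this
pairing yields rho >= 0 for every gene (rho = 1 exactly whenever both
vectors are tie-free); it measures distributional concordance, with ties at
low expression driving rho below 1.  The anticorrelated class labels are
part of the classification rule and record schema (classes follow the sign
of rho and an unadjusted 0.05 threshold: correlated_sig / correlated_ns for
rho >= 0, anticorrelated_sig / anticorrelated_ns for rho < 0, undefined for
rho = NaN) but cannot be populated by the quantile pairing itself; they are
reachable only through future pairing strategies with a shared sample axis.
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import rowwise_spearman_paired
from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleMetadata,
    Unit,
    strip_version,
)

__all__ = [
    "per_gene_correlation",
    "classify",
    "class_overlap",
    "overrepresentation",
    "GENE_CLASSES",
]

logger = logging.getLogger(__name__)

GENE_CLASSES = (
    "correlated_sig",
    "correlated_ns",
    "anticorrelated_sig",
    "anticorrelated_ns",
    "undefined",
)

_ADJUST_METHODS = {"bh": "fdr_bh", "bonferroni": "bonferroni"}


def classify(rho: float, p: float, alpha: float = 0.05) -> str:
    if np.isnan(rho):
        return "undefined"
    sig = p < alpha
    if rho >= 0:
        return "correlated_sig" if sig else "correlated_ns"
    return "anticorrelated_sig" if sig else "anticorrelated_ns"


def per_gene_correlation(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    model_samples: Sequence[str] | dict,
    tissue_samples: Sequence[str] | dict,
    alpha: float = 0.05,
    pairing: str = "quantile",
    model_group: str = "model",
    tissue_group: str = "tissue",
) -> pd.DataFrame:
    """Quantile-paired per-gene Spearman correlation between two groups.

    ``model_samples`` / ``tissue_samples`` are either explicit sample-ID lists
    or metadata filter dicts passed to :meth:`SampleMetadata.select`.  The two
    groups must be disjoint and each contain at least 3 samples.

    Returns a DataFrame with columns (gene_id, rho, p, n_pairs, class,
    model_group, tissue_group).
    """
    if matrix.unit != Unit.tpm:
        raise ValueError("per_gene_correlation expects a TPM matrix")
    if pairing != "quantile":
        raise ValueError(f"unknown pairing strategy {pairing!r}")

    def _resolve(sel) -> list[str]:
        if isinstance(sel, dict):
            return sorted(meta.select(**sel)["sample_id"])
        return list(sel)

    mids = _resolve(model_samples)
    tids = _resolve(tissue_samples)
    overlap = set(mids) & set(tids)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:10]}")
    if len(mids) < 3 or len(tids) < 3:
        raise ValueError("each group needs >= 3 samples")
    a = matrix.values.loc[:, mids].to_numpy(dtype=float)
    b = matrix.values.loc[:, tids].to_numpy(dtype=float)
    n = min(a.shape[1], b.shape[1])
    probs = np.linspace(0.0, 1.0, n)
    qa = np.quantile(a, probs, axis=1).T  # genes x n, type-7 interpolation
    qb = np.quantile(b, probs, axis=1).T
    const = np.all(a == a[:, :1], axis=1) | np.all(b == b[:, :1], axis=1)
    rho, p = rowwise_spearman_paired(qa, qb)
    rho[const] = np.nan
    p[const] = np.nan
    classes = [classify(r, pp, alpha) for r, pp in zip(rho, p)]
    return pd.DataFrame(
        {
            "gene_id": matrix.stripped_index(),
            "rho": rho,
            "p": p,
            "n_pairs": n,
            "class": classes,
            "model_group": model_group,
            "tissue_group": tissue_group,
        }
    )


def class_overlap(
    records_a: pd.DataFrame, records_b: pd.DataFrame, gene_class: str
) -> tuple[set[str], set[str], set[str]]:
    """Partition the genes of ``gene_class``: (only in a, only in b, both).

    Both record tables must cover the same gene universe.
    """
    if gene_class not in GENE_CLASSES:
        raise ValueError(f"unknown class {gene_class!r}")
    ua = set(records_a["gene_id"])
    ub = set(records_b["gene_id"])
    if ua != ub:
        raise ValueError(
            f"gene universe mismatch: {len(ua - ub)} genes only in a, "
            f"{len(ub - ua)} only in b"
        )
    ga = set(records_a.loc[records_a["class"] == gene_class, "gene_id"])
    gb = set(records_b.loc[records_b["class"] == gene_class, "gene_id"])
    return ga - gb, gb - ga, ga & gb


def overrepresentation(
    query: Sequence[str],
    collection: GeneSetCollection,
    universe: Sequence[str],
    adjust: str = "bh",
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    For each set (intersected with the universe first), the upper-tail
    probability of drawing >= k set members in a size-q query from a size-N
    universe containing s set members.  ``recall`` is k divided by the
    in-universe set size.  Results are sorted by adjusted p, then set name.
    """
    if adjust not in _ADJUST_METHODS:
        raise ValueError(f"unknown adjustment {adjust!r}")
    universe_set = {strip_version(g) for g in universe}
    query_set = {strip_version(g) for g in query}
    if not query_set or not universe_set:
        raise ValueError("query and universe must be non-empty")
    if not query_set <= universe_set:
        raise ValueError(
            f"query contains {len(query_set - universe_set)} genes outside the universe"
        )
    n_univ = len(universe_set)
    q = len(query_set)
    rows = []
    for gs in collection:
        members = set(gs.genes) & universe_set
        s = len(members)
        k = len(members & query_set)
        if s == 0:
            logger.warning("set %s has no members in the universe; skipped", gs.name)
            continue
        p = float(stats.hypergeom.sf(k - 1, n_univ, s, q))
        rows.append(
            {
                "set_name": gs.name,
                "overlap": k,
                "query_size": q,
                "set_size": s,
                "universe_size": n_univ,
                "recall": k / s,
                "p_raw": min(1.0, p),
            }
        )
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method=_ADJUST_METHODS[adjust])[1]
    return out.sort_values(["p_adj", "set_name"], kind="mergesort").reset_index(drop=True)
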
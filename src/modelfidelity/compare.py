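"""Model-type comparisons: cell line vs PDX rank-sum tests per tissue group.

The test statistic is reported in the Mann-Whitney U convention: U is the
rank-sum of the first sample (cell lines) minus n1(n1+1)/2.  The classical
rank-sum W of the first sample is U + n1(n1+1)/2 and is included in the
output for cross-checking against R conventions.  Exact p-values are used for
small tie-free samples, otherwise a normal approximation with tie and
continuity corrections.
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ModelType, SampleMetadata

__all__ = ["wilcoxon_rank_sum", "compare_model_types", "COMPARISON_COLUMNS"]

logger = logging.getLogger(__name__)

EXACT_TOTAL_N = 20

COMPARISON_COLUMNS = [
    "tissue_group",
    "disease_state",
    "n_cell_line",
    "n_pdx",
    "median_rho_cell_line",
    "median_rho_pdx",
    "U",
    "W",
    "p_raw",
    "p_adj",
    "winner",
]


def wilcoxon_rank_sum(a, b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of ``a``.
    ``mode='exact'`` enumerates the null distribution (valid without ties),
    ``'normal_approx'`` uses the tie- and continuity-corrected normal
    approximation, and ``'auto'`` picks exact when ``len(a)+len(b) <= 20``
    and there are no ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("wilcoxon_rank_sum requires non-empty samples")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if mode == "auto":
        method = "exact" if (a.size + b.size <= EXACT_TOTAL_N and not has_ties) else "asymptotic"
    elif mode == "exact":
        method = "exact"
    elif mode == "normal_approx":
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def compare_model_types(
    records: pd.DataFrame,
    meta: SampleMetadata,
    alpha: float = 0.05,
    min_per_type: int = 3,
    mode: str = "auto",
) -> pd.DataFrame:
    """Rank-sum comparison of cell-line vs PDX rho_median per tissue group.

    For every (tissue_group, disease_state) present in ``records``, the
    per-model-sample rho_median values of the two model types are compared
    with :func:`wilcoxon_rank_sum`; p-values are Bonferroni-adjusted within
    the family of all performed comparisons.  A winner (the model type with
    the higher median) is declared only when the adjusted p falls below
    ``alpha``.  Groups with fewer than ``min_per_type`` samples of either
    type are skipped with a warning.
    """
    merged = records.merge(
        meta.table[["sample_id", "model_type"]].rename(
            columns={"sample_id": "model_sample_id"}
        ),
        on="model_sample_id",
        how="left",
    )
    known = {ModelType.cell_line.value, ModelType.pdx.value}
    types_seen = set(merged["model_type"].dropna().unique())
    unknown = types_seen - known - {ModelType.tissue.value}
    if unknown or merged["model_type"].isna().any():
        raise ValueError(f"records contain samples with unknown model types: {unknown}")
    rows = []
    for (tg, ds), grp in merged.groupby(["tissue_group", "disease_state"], sort=True):
        cl = grp.loc[grp["model_type"] == ModelType.cell_line.value, "rho_median"].to_numpy()
        px = grp.loc[grp["model_type"] == ModelType.pdx.value, "rho_median"].to_numpy()
        if cl.size < min_per_type or px.size < min_per_type:
            logger.warning(
                "comparison skipped for (%s, %s): %d cell lines, %d PDXs",
                tg, ds, cl.size, px.size,
            )
            continue
        u, p = wilcoxon_rank_sum(cl, px, mode=mode)
        rows.append(
            {
                "tissue_group": tg,
                "disease_state": ds,
                "n_cell_line": int(cl.size),
                "n_pdx": int(px.size),
                "median_rho_cell_line": float(np.median(cl)),
                "median_rho_pdx": float(np.median(px)),
                "U": u,
                "W": u + cl.size * (cl.size + 1) / 2.0,
                "p_raw": p,
            }
        )
    if not rows:
        raise ValueError("no tissue group had enough samples of both model types")
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_adj"] = np.minimum(1.0, out["p_raw"] * m)
    winner = np.where(
        out["p_adj"] < alpha,
        np.where(
            out["median_rho_cell_line"] > out["median_rho_pdx"],
            ModelType.cell_line.value,
            ModelType.pdx.value,
        ),
        "none",
    )
    # equal medians with a significant p: no direction, no winner
    winner = np.where(
        (out["p_adj"] < alpha)
        & (out["median_rho_cell_line"] == out["median_rho_pdx"]),
        "none",
        winner,
    )
    out["winner"] = winner
    return out[COMPARISON_COLUMNS]
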
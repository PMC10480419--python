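"""Shared rank-statistics helpers.

Spearman's rho is the Pearson correlation of average-rank-transformed values;
two-sided p-values use the t approximation t = rho * sqrt((n-2)/(1-rho^2)) on
n-2 degrees of freedom.  Constant inputs have undefined rho (returned as NaN).
"""
from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = [
    "SpearmanResult",
    "spearman",
    "spearman_p",
    "rank_columns",
    "spearman_matrix",
    "rowwise_spearman_vs_vector",
    "rowwise_spearman_paired",
]


class SpearmanResult(NamedTuple):
    rho: float
    p: float

    @property
    def defined(self) -> bool:
        return not np.isnan(self.rho)


def spearman_p(rho, n):
    """Two-sided p for Spearman rho via the t approximation (n-2 d.f.)."""
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 1.0 - rho**2
        t = rho * np.sqrt((n - 2) / np.where(denom <= 0, np.nan, denom))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    # |rho| == 1 gives an infinite t statistic -> p = 0
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    p = np.where(np.isnan(rho), np.nan, p)
    if p.ndim == 0:
        return float(p)
    return p


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation of two vectors with average ranks for ties.

    Returns ``(nan, nan)`` when either vector is constant (rho undefined).
    Raises on length mismatch or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError(f"spearman requires n >= 3, got n={n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(float("nan"), float("nan"))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = float(np.clip(rho, -1.0, 1.0))
    return SpearmanResult(rho, spearman_p(rho, n))


def rank_columns(a: np.ndarray) -> np.ndarray:
    """Average-rank transform of each column of a 2-D array."""
    return stats.rankdata(a, axis=0)


def _standardize_columns(a: np.ndarray) -> np.ndarray:
    """Center columns and scale to unit norm; constant columns become NaN."""
    centered = a - a.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return centered / np.where(norms == 0, np.nan, norms)


def spearman_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Spearman rho between columns of ``a`` and columns of ``b``.

    Both arrays share the row (gene) axis.  Returns an (a_cols x b_cols)
    matrix; entries involving a constant column are NaN.
    """
    za = _standardize_columns(rank_columns(a))
    zb = _standardize_columns(rank_columns(b))
    rho = za.T @ zb
    return np.clip(rho, -1.0, 1.0)


def rowwise_spearman_vs_vector(x: np.ndarray, y: np.ndarray):
    """Spearman rho (and p) of each row of ``x`` against the vector ``y``.

    Rows that are constant get NaN rho/p; ``y`` must be non-constant.
    """
    n = y.size
    ry = stats.rankdata(y)
    zy = ry - ry.mean()
    ynorm = np.linalg.norm(zy)
    if ynorm == 0:
        raise ValueError("comparison vector is constant")
    zy = zy / ynorm
    rx = stats.rankdata(x, axis=1)
    zx = _standardize_columns(rx.T).T  # standardize along rows
    rho = np.clip(zx @ zy, -1.0, 1.0)
    return rho, spearman_p(rho, n)


def rowwise_spearman_paired(a: np.ndarray, b: np.ndarray):
    """Spearman rho (and p) of paired rows: row i of ``a`` vs row i of ``b``."""
    if a.shape != b.shape:
        raise ValueError("paired arrays must have identical shapes")
    n = a.shape[1]
    ra = stats.rankdata(a, axis=1)
    rb = stats.rankdata(b, axis=1)
    za = _standardize_columns(ra.T).T
    zb = _standardize_columns(rb.T).T
    rho = np.clip(np.sum(za * zb, axis=1), -1.0, 1.0)
    return rho, spearman_p(rho, n)
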
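"""Synthetic bulk RNA-seq cohorts with known ground truth.

The generator emulates the statistical structure the fidelity analysis
assumes, at desk scale:

* several tissues, each with a tissue-identity expression signal and a small
  panel of tissue-specific marker genes (high and low);
* non-diseased tissue samples and tumor samples, where each bulk tumor is a
  linear-scale admixture of a malignant (tumor-cell) profile and a stromal
  profile in proportion to a latent Beta-distributed purity.  The two
  compartment profiles share the tissue's tumor base profile and differ only
  at the purity-responsive genes ('+' genes elevated in the malignant
  compartment, '-' genes elevated in the stroma), so that exactly those
  genes correlate with purity across tumors;
* preclinical model samples (cell lines, PDXs) that carry the pure tumor-cell
  profile of their origin tissue plus a model-class-specific log-scale drift,
  making model fidelity a tunable dial (larger drift = lower fidelity);
* negative-binomial counts with log-normal library-size factors, so the TPM
  conversion and all downstream statistics exercise the real pipeline path.

Everything is deterministic given the master seed: each generation stage
draws from its own fixed substream, so adding stages never reshuffles
earlier draws.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleMetadata,
    Unit,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "default_config",
    "zero_drift_config",
    "null_config",
]

# fixed substream labels (seed offsets); order is frozen
_STAGES = {
    "baseline": 0,
    "tissue_shift": 1,
    "tumor_shift": 2,
    "normals": 3,
    "tumors": 4,
    "models": 5,
    "library": 6,
    "counts": 7,
}

_POISSON_DISPERSION = 1e6  # NB size above this is treated as the Poisson limit


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Expression effects are on the log2 scale.  ``tissue_signal_sd`` is the
    s.d. of the random per-(tissue, gene) identity shift; tissue-specific
    marker genes get a deterministic shift of +/- 3 x tissue_signal_sd.
    ``tumor_signal_sd`` is the s.d. of the per-(tissue, gene) malignant
    program shift that separates a tissue's tumor state from its non-diseased
    state.  ``purity_effect`` is the log2 up-shift of purity-responsive genes
    in the tumor-cell profile ('+' direction) or the stromal profile ('-'
    direction).  ``drift_*`` are the s.d.s of the gene-wise log2 perturbation
    each model sample acquires relative to its origin tumor-cell profile.
    ``dispersion`` is the negative-binomial size parameter (large values
    approach the Poisson limit).
    """

    n_tissues: int = 3
    genes_total: int = 2000
    genes_tissue_specific_per_tissue: int = 40  # split evenly into high / low
    genes_purity_responsive: int = 100  # split evenly into '+' / '-'
    n_normal_per_tissue: int = 20
    n_tumor_per_tissue: int = 30
    n_cell_line_per_tissue: int = 20
    n_pdx_per_tissue: int = 20
    purity_beta_params: tuple[float, float] = (4.0, 1.5)
    drift_cell_line: float = 1.0
    drift_pdx: float = 0.3
    tissue_signal_sd: float = 1.0
    tumor_signal_sd: float = 1.0
    purity_effect: float = 3.0
    noise_sd: float = 0.3
    baseline_log_mean_range: tuple[float, float] = (3.0, 10.0)
    #: Purity-responsive genes are drawn as abundant transcripts (top of the
    #: baseline range), emulating the immune/stromal/proliferation programs
    #: that dominate bulk purity signatures.
    purity_gene_log_mean_range: tuple[float, float] = (8.0, 10.0)
    dispersion: float = 20.0
    library_sd: float = 0.2
    gene_length_bp: float = 1000.0
    seed: int = 1

    def validate(self) -> None:
        if self.n_tissues < 2:
            raise ValueError("n_tissues must be >= 2")
        if self.genes_tissue_specific_per_tissue % 2 != 0:
            raise ValueError("genes_tissue_specific_per_tissue must be even")
        if self.genes_purity_responsive % 2 != 0:
            raise ValueError("genes_purity_responsive must be even")
        reserved = (
            self.n_tissues * self.genes_tissue_specific_per_tissue
            + self.genes_purity_responsive
        )
        if reserved > self.genes_total:
            raise ValueError(
                f"tissue-specific + purity-responsive genes ({reserved}) exceed "
                f"genes_total ({self.genes_total})"
            )
        if self.drift_cell_line < 0 or self.drift_pdx < 0:
            raise ValueError("drift values must be >= 0")
        a, b = self.purity_beta_params
        if a <= 0 or b <= 0:
            raise ValueError("purity_beta_params must be positive")
        if self.noise_sd < 0 or self.tissue_signal_sd < 0 or self.tumor_signal_sd < 0:
            raise ValueError("signal/noise s.d.s must be >= 0")
        lo, hi = self.baseline_log_mean_range
        if hi <= lo:
            raise ValueError("baseline_log_mean_range must satisfy lo < hi")
        plo, phi = self.purity_gene_log_mean_range
        if phi <= plo:
            raise ValueError("purity_gene_log_mean_range must satisfy lo < hi")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for field in (
            "n_normal_per_tissue",
            "n_tumor_per_tissue",
            "n_cell_line_per_tissue",
            "n_pdx_per_tissue",
        ):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be >= 0")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def default_config(**overrides) -> SimulationConfig:
    return SimulationConfig(**overrides)


def zero_drift_config(**overrides) -> SimulationConfig:
    """Noise-free, zero-drift limit: models are exact copies of their origin
    tumor-cell profile up to (near-Poisson) counting noise."""
    base = dict(
        drift_cell_line=0.0,
        drift_pdx=0.0,
        noise_sd=0.0,
        dispersion=1e9,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def null_config(**overrides) -> SimulationConfig:
    """Null for type-I-error checks: both model classes drift equally and no
    gene responds to purity."""
    base = dict(
        drift_cell_line=0.5,
        drift_pdx=0.5,
        genes_purity_responsive=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@dataclasses.dataclass
class GroundTruth:
    """Latent quantities of a simulated cohort, for recovery tests.

    ``purity_direction`` maps each purity-responsive gene to +1 (expression
    rises with purity; elevated in the tumor-cell profile) or -1 (expression
    falls with purity; elevated in the stromal profile).
    ``tumor_cell_profiles`` holds the log2 malignant profile per tissue —
    the profile every model sample of that tissue drifts around.
    """

    tissue_specific_high: dict[str, list[str]]
    tissue_specific_low: dict[str, list[str]]
    purity_direction: pd.Series
    purity: pd.Series
    model_origin: pd.DataFrame
    tumor_cell_profiles: pd.DataFrame
    stromal_profiles: pd.DataFrame

    def gene_sets(self) -> GeneSetCollection:
        """Ground-truth tissue-specific sets as a GMT-ready collection."""
        sets: dict[str, list[str]] = {}
        for t, genes in self.tissue_specific_high.items():
            sets[f"{t}_high"] = list(genes)
        for t, genes in self.tissue_specific_low.items():
            sets[f"{t}_low"] = list(genes)
        return GeneSetCollection.from_dict(
            sets, descriptions={n: "ground-truth tissue-specific set" for n in sets}
        )


def _rng(cfg: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), _STAGES[stage]])


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    if size_param >= _POISSON_DISPERSION:
        return rng.poisson(mean)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, GroundTruth]:
    """Generate a cohort of counts, metadata and ground truth.

    Deterministic given ``cfg`` (including its seed): two calls with the same
    config return bit-identical outputs.
    """
    cfg.validate()
    g = cfg.genes_total
    tissues = [f"tissue{t + 1}" for t in range(cfg.n_tissues)]
    gene_ids = [f"ENSG{i:08d}" for i in range(1, g + 1)]

    # --- gene role assignment (deterministic blocks) -------------------------
    half_ts = cfg.genes_tissue_specific_per_tissue // 2
    ts_high: dict[str, list[str]] = {}
    ts_low: dict[str, list[str]] = {}
    pos = 0
    for t in tissues:
        ts_high[t] = gene_ids[pos : pos + half_ts]
        pos += half_ts
        ts_low[t] = gene_ids[pos : pos + half_ts]
        pos += half_ts
    half_pur = cfg.genes_purity_responsive // 2
    plus_genes = gene_ids[pos : pos + half_pur]
    pos += half_pur
    minus_genes = gene_ids[pos : pos + half_pur]
    pos += half_pur
    gene_index = pd.Index(gene_ids)
    idx_of = {gid: i for i, gid in enumerate(gene_ids)}

    # --- latent profiles (log2 scale) ---------------------------------------
    lo, hi = cfg.baseline_log_mean_range
    rng_base = _rng(cfg, "baseline")
    mu = rng_base.uniform(lo, hi, size=g)
    pur_idx = [idx_of[x] for x in plus_genes + minus_genes]
    if pur_idx:
        plo, phi = cfg.purity_gene_log_mean_range
        mu[pur_idx] = rng_base.uniform(plo, phi, size=len(pur_idx))

    delta = 3.0 * cfg.tissue_signal_sd
    tshift = _rng(cfg, "tissue_shift").normal(0.0, cfg.tissue_signal_sd, size=(cfg.n_tissues, g))
    for ti, t in enumerate(tissues):
        tshift[ti, [idx_of[x] for x in ts_high[t]]] = delta
        tshift[ti, [idx_of[x] for x in ts_low[t]]] = -delta

    tumor_shift = _rng(cfg, "tumor_shift").normal(0.0, cfg.tumor_signal_sd, size=(cfg.n_tissues, g))

    plus_idx = [idx_of[x] for x in plus_genes]
    minus_idx = [idx_of[x] for x in minus_genes]
    tumor_cell = np.empty((cfg.n_tissues, g))
    stromal = np.empty((cfg.n_tissues, g))
    for ti in range(cfg.n_tissues):
        base = mu + tshift[ti] + tumor_shift[ti]
        tumor_cell[ti] = base
        tumor_cell[ti, plus_idx] += cfg.purity_effect
        stromal[ti] = base
        stromal[ti, minus_idx] += cfg.purity_effect

    # --- samples -------------------------------------------------------------
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    log_or_linear_means: list[np.ndarray] = []  # linear-scale expected expression

    rng_norm = _rng(cfg, "normals")
    rng_tum = _rng(cfg, "tumors")
    rng_mod = _rng(cfg, "models")

    purities: dict[str, float] = {}
    model_rows: list[dict] = []

    def _noise(rng: np.random.Generator) -> np.ndarray:
        if cfg.noise_sd == 0:
            return np.zeros(g)
        return rng.normal(0.0, cfg.noise_sd, size=g)

    for ti, t in enumerate(tissues):
        for i in range(cfg.n_normal_per_tissue):
            sid = f"{t}_normal_{i:03d}"
            logmean = mu + tshift[ti] + _noise(rng_norm)
            sample_ids.append(sid)
            log_or_linear_means.append(np.exp2(logmean))
            meta_rows.append(
                dict(sample_id=sid, source="synthetic", tissue_group=t,
                     disease_state="non_diseased", model_type="tissue", purity=np.nan)
            )
        for i in range(cfg.n_tumor_per_tissue):
            sid = f"{t}_tumor_{i:03d}"
            p = float(rng_tum.beta(*cfg.purity_beta_params))
            linear = p * np.exp2(tumor_cell[ti]) + (1.0 - p) * np.exp2(stromal[ti])
            linear = linear * np.exp2(_noise(rng_tum))
            sample_ids.append(sid)
            log_or_linear_means.append(linear)
            purities[sid] = p
            meta_rows.append(
                dict(sample_id=sid, source="synthetic", tissue_group=t,
                     disease_state="tumor", model_type="tissue", purity=p)
            )
        for model_type, n_model, drift_sd, tag in (
            ("cell_line", cfg.n_cell_line_per_tissue, cfg.drift_cell_line, "cl"),
            ("pdx", cfg.n_pdx_per_tissue, cfg.drift_pdx, "pdx"),
        ):
            for i in range(n_model):
                sid = f"{t}_{tag}_{i:03d}"
                drift = (
                    rng_mod.normal(0.0, drift_sd, size=g) if drift_sd > 0 else np.zeros(g)
                )
                logmean = tumor_cell[ti] + drift + _noise(rng_mod)
                sample_ids.append(sid)
                log_or_linear_means.append(np.exp2(logmean))
                meta_rows.append(
                    dict(sample_id=sid, source="synthetic", tissue_group=t,
                         disease_state="tumor", model_type=model_type, purity=np.nan)
                )
                model_rows.append(
                    dict(sample_id=sid, origin_tissue=t, model_type=model_type,
                         drift_sd=drift_sd)
                )

    means = np.column_stack(log_or_linear_means)  # genes x samples
    lib = np.exp(_rng(cfg, "library").normal(0.0, cfg.library_sd, size=len(sample_ids)))
    counts = _nb_counts(_rng(cfg, "counts"), means * lib[None, :], cfg.dispersion)

    values = pd.DataFrame(
        counts.astype(float), index=gene_index, columns=sample_ids
    )
    lengths = pd.Series(cfg.gene_length_bp, index=gene_index, name="length_bp")
    matrix = ExpressionMatrix(values, Unit.counts, lengths)
    meta = SampleMetadata(pd.DataFrame(meta_rows))

    direction = pd.Series(
        [1] * len(plus_genes) + [-1] * len(minus_genes),
        index=plus_genes + minus_genes,
        dtype=int,
        name="purity_direction",
    )
    truth = GroundTruth(
        tissue_specific_high=ts_high,
        tissue_specific_low=ts_low,
        purity_direction=direction,
        purity=pd.Series(purities, name="purity"),
        model_origin=pd.DataFrame(model_rows),
        tumor_cell_profiles=pd.DataFrame(
            tumor_cell.T, index=gene_index, columns=tissues
        ),
        stromal_profiles=pd.DataFrame(stromal.T, index=gene_index, columns=tissues),
    )
    return matrix, meta, truth
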
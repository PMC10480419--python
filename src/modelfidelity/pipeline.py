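"""End-to-end orchestration: simulate -> TPM -> subsets -> correlate ->
specificity -> compare -> per-gene correlation -> enrichment -> PCA, driven
by a single flat YAML config, with a machine-readable run manifest.

Every stage writes its outputs before the next starts; all randomness flows
from the single config seed, so a rerun with an identical config produces
byte-identical outputs (the manifest records a SHA-256 checksum per file).
Unknown config keys are errors, not warnings: silent typos in analysis
configs are the classic reproducibility failure.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .compare import compare_model_types
from .containers import DiseaseState, ExpressionMatrix, ModelType, SampleMetadata, Unit
from .correlate import model_to_tissue, pca_qc, specificity
from .genecorr import overrepresentation, per_gene_correlation
from .normalize import counts_to_tpm, log_transform
from .simulate import SimulationConfig, simulate_cohort
from .subsets import exclude_genes, purity_correlated_genes, tissue_specific_sets, top_variable_genes

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "tpm",
    "subsets",
    "correlate",
    "specificity",
    "compare",
    "gene_corr",
    "enrich",
    "pca",
)

_FLOAT_FMT = "%.10g"


@dataclasses.dataclass
class RunConfig:
    """Typed, flat run configuration.

    Either ``simulate`` holds :class:`SimulationConfig` overrides, or
    ``expression``/``metadata`` (and ``lengths`` for counts) point at input
    files.  ``subset_sizes`` lists the most-variable-gene subset sizes to
    evaluate in addition to the full gene set; sizes exceeding the gene count
    are dropped with a warning.  ``purity_mode`` controls whether correlation
    runs include purity-correlated genes, exclude them, or both.
    """

    seed: int = 1
    out_dir: str = "run_out"
    stages: tuple[str, ...] = ALL_STAGES
    simulate: dict | None = None
    expression: str | None = None
    expression_unit: str = "counts"
    lengths: str | None = None
    metadata: str | None = None
    subset_sizes: tuple[int, ...] = (100, 1000, 5000, 10000)
    purity_mode: str = "both"  # include | exclude | both
    variance_reference: str = "tumor"  # tumor | non_diseased
    alpha: float = 0.05
    adjust: str = "bh"
    min_abs_rho: float = 0.3
    z_threshold: float = 3.0
    gene_corr_tissue: str | None = None
    pca_components: int = 5
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.purity_mode not in ("include", "exclude", "both"):
            raise ValueError(f"invalid purity_mode {self.purity_mode!r}")
        if self.variance_reference not in ("tumor", "non_diseased"):
            raise ValueError(f"invalid variance_reference {self.variance_reference!r}")
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        sizes = list(self.subset_sizes)
        if any(k <= 0 for k in sizes):
            raise ValueError("subset_sizes must be positive")
        if sorted(set(sizes)) != sizes:
            raise ValueError("subset_sizes must be unique and ascending")
        if self.simulate is None and "simulate" in self.stages:
            self.simulate = {}
        if self.simulate is None and (self.expression is None or self.metadata is None):
            raise ValueError("config needs either 'simulate' or input file paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        if "stages" in raw:
            raw = {**raw, "stages": tuple(raw["stages"])}
        if "subset_sizes" in raw:
            raw = {**raw, "subset_sizes": tuple(raw["subset_sizes"])}
        if "simulate" in raw and raw["simulate"] is not None:
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            sim_unknown = sorted(set(raw["simulate"]) - sim_known)
            if sim_unknown:
                raise ValueError(f"unknown simulate config keys: {sim_unknown}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    package_version: str
    files: dict[str, str]  # relative path -> sha256
    timings: dict[str, float]
    warnings: list[str]

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(f"{record.name}: {record.getMessage()}")


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> RunManifest:
    """Execute the enabled stages in dependency order and write a manifest.

    Failures abort with the stage name; outputs written so far are preserved.
    Returns the manifest (also written to ``run_manifest.json``).
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    logging.getLogger("modelfidelity").addHandler(collector)
    files: dict[str, str] = {}
    timings: dict[str, float] = {}

    def _register(path: Path) -> None:
        files[str(path.relative_to(out))] = _sha256(path)

    def _write_df(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)
        _register(path)

    def _write_json(obj, name: str) -> None:
        path = out / name
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
            fh.write("\n")
        _register(path)

    state: dict[str, Any] = {}
    try:
        for stage in ALL_STAGES:
            if stage not in cfg.stages:
                continue
            t0 = time.perf_counter()
            _run_stage(stage, cfg, out, state, _register, _write_df, _write_json)
            timings[stage] = round(time.perf_counter() - t0, 4)
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logging.getLogger("modelfidelity").removeHandler(collector)

    manifest = RunManifest(
        config_hash=cfg.config_hash(),
        package_version=__version__,
        files=files,
        timings=timings,
        warnings=collector.messages,
    )
    manifest.write(out / "run_manifest.json")
    return manifest


def _load_inputs(cfg: RunConfig, state: dict) -> None:
    if "counts" in state or "tpm" in state:
        return
    if cfg.expression is None or cfg.metadata is None:
        raise ValueError("no simulated data and no input files configured")
    unit = Unit(cfg.expression_unit)
    matrix = io.read_expression(cfg.expression, unit, lengths_path=cfg.lengths)
    state["meta"] = io.read_metadata(cfg.metadata)
    if unit == Unit.counts:
        state["counts"] = matrix
    else:
        state["tpm"] = matrix


def _matched_tumor_median(records: pd.DataFrame, meta: SampleMetadata) -> float:
    m = records.merge(
        meta.table[["sample_id", "tissue_group"]].rename(
            columns={"sample_id": "model_sample_id", "tissue_group": "origin"}
        ),
        on="model_sample_id",
    )
    m = m[(m["tissue_group"] == m["origin"]) & (m["disease_state"] == DiseaseState.tumor.value)]
    return float(m["rho_median"].median())


def _run_stage(stage, cfg: RunConfig, out: Path, state: dict, _register, _write_df, _write_json) -> None:
    if stage == "simulate":
        sim_cfg = SimulationConfig(**{"seed": cfg.seed, **(cfg.simulate or {})})
        counts, meta, truth = simulate_cohort(sim_cfg)
        state.update(counts=counts, meta=meta, truth=truth)
        io.write_expression(counts, out / "expression.tsv")
        _register(out / "expression.tsv")
        io.write_gene_lengths(counts.gene_lengths, out / "lengths.tsv")
        _register(out / "lengths.tsv")
        io.write_metadata(meta, out / "metadata.tsv")
        _register(out / "metadata.tsv")
        truth_json = {
            "tissue_specific_high": truth.tissue_specific_high,
            "tissue_specific_low": truth.tissue_specific_low,
            "purity_direction": {g: int(d) for g, d in truth.purity_direction.items()},
            "purity": {s: float(p) for s, p in truth.purity.items()},
            "model_origin": truth.model_origin.to_dict(orient="records"),
        }
        _write_json(truth_json, "truth.json")
        io.write_gmt(truth.gene_sets(), out / "gene_sets_truth.gmt")
        _register(out / "gene_sets_truth.gmt")
        return

    if stage == "tpm":
        _load_inputs(cfg, state)
        if "tpm" not in state:
            state["tpm"] = counts_to_tpm(state["counts"])
            io.write_expression(state["tpm"], out / "tpm.tsv")
            _register(out / "tpm.tsv")
        state["log"] = log_transform(state["tpm"])
        return

    _load_inputs(cfg, state)
    if "tpm" not in state:
        raise ValueError("missing upstream output: run the 'tpm' stage first")
    if "log" not in state:
        state["log"] = log_transform(state["tpm"])
    tpm: ExpressionMatrix = state["tpm"]
    logm: ExpressionMatrix = state["log"]
    meta: SampleMetadata = state["meta"]

    if stage == "subsets":
        ref_state = cfg.variance_reference
        ref = meta.select(model_type=ModelType.tissue.value, disease_state=ref_state)
        ref_ids = sorted(set(ref["sample_id"]) & set(tpm.sample_ids))
        subsets = {}
        for k in cfg.subset_sizes:
            if k > tpm.n_genes:
                logger.warning("subset size %d exceeds gene count %d; dropped", k, tpm.n_genes)
                continue
            sub = top_variable_genes(
                logm, k, sample_ids=ref_ids, reference_cohort=ref_state
            )
            subsets[sub.name] = sub
            io.write_gene_list(sub.gene_ids, out / f"{sub.name}.txt")
            _register(out / f"{sub.name}.txt")
        state["variance_subsets"] = subsets
        try:
            purity_res = purity_correlated_genes(
                tpm, meta, alpha=cfg.alpha, adjust=cfg.adjust, min_abs_rho=cfg.min_abs_rho
            )
            state["purity_result"] = purity_res
            for cohort, df in purity_res.per_cohort.items():
                _write_df(df, f"purity_{cohort}.tsv")
            io.write_gene_list(purity_res.union.gene_ids, out / "purity_union.txt")
            _register(out / "purity_union.txt")
        except ValueError as exc:
            logger.warning("purity detection skipped: %s", exc)
        try:
            tissue_sets = tissue_specific_sets(logm, meta, z_threshold=cfg.z_threshold)
            state["tissue_sets"] = tissue_sets
            io.write_gmt(tissue_sets, out / "tissue_specific.gmt")
            _register(out / "tissue_specific.gmt")
        except ValueError as exc:
            logger.warning("tissue-specific sets skipped: %s", exc)
        return

    if stage == "correlate":
        runs: list[tuple[str, Any]] = [("full_set", None)]
        for name, sub in state.get("variance_subsets", {}).items():
            runs.append((name, sub))
        purity_union = getattr(state.get("purity_result"), "union", None)
        frames = []
        for name, sub in runs:
            if cfg.purity_mode in ("include", "both"):
                frames.append(model_to_tissue(tpm, meta, subset=sub))
            if cfg.purity_mode in ("exclude", "both") and purity_union is not None:
                base = list(tpm.stripped_index()) if sub is None else sub
                ex = exclude_genes(base, purity_union, name=f"{name}_no_purity")
                frames.append(model_to_tissue(tpm, meta, subset=ex))
        records = pd.concat(frames, ignore_index=True)
        state["records"] = records
        _write_df(records, "correlations.tsv")
        return

    if stage == "specificity":
        if "records" not in state:
            raise ValueError("missing upstream output: run the 'correlate' stage first")
        summary = {}
        matched = {}
        for name, grp in state["records"].groupby("gene_subset"):
            s = specificity(grp, meta)
            summary[name] = s.to_dict()
            matched[name] = _matched_tumor_median(grp, meta)
            state.setdefault("specificity", {})[name] = s
        _write_json(
            {"per_subset": summary, "matched_tumor_rho_median": matched},
            "specificity.json",
        )
        full = state["specificity"].get("full_set")
        if full is not None:
            _write_df(full.group_medians, "group_medians_full_set.tsv")
        return

    if stage == "compare":
        if "records" not in state:
            raise ValueError("missing upstream output: run the 'correlate' stage first")
        full = state["records"]
        full = full[full["gene_subset"] == "full_set"]
        if full.empty:
            full = state["records"][
                state["records"]["gene_subset"] == state["records"]["gene_subset"].iloc[0]
            ]
        comp = compare_model_types(full, meta, alpha=cfg.alpha)
        state["comparisons"] = comp
        _write_df(comp, "comparisons.tsv")
        return

    if stage == "gene_corr":
        tissue = cfg.gene_corr_tissue
        if tissue is None:
            tumor_groups = meta.select(
                model_type=ModelType.tissue.value, disease_state=DiseaseState.tumor.value
            )["tissue_group"]
            if tumor_groups.empty:
                raise ValueError("no tumor tissue groups for per-gene correlation")
            tissue = sorted(tumor_groups.unique())[0]
        state["gene_corr"] = {}
        for model_type in (ModelType.cell_line.value, ModelType.pdx.value):
            mids = meta.select(model_type=model_type, tissue_group=tissue)["sample_id"]
            tids = meta.select(
                model_type=ModelType.tissue.value,
                disease_state=DiseaseState.tumor.value,
                tissue_group=tissue,
            )["sample_id"]
            mids = sorted(set(mids) & set(tpm.sample_ids))
            tids = sorted(set(tids) & set(tpm.sample_ids))
            if len(mids) < 3 or len(tids) < 3:
                logger.warning(
                    "gene_corr skipped for %s/%s: too few samples", model_type, tissue
                )
                continue
            df = per_gene_correlation(
                tpm, meta, mids, tids,
                model_group=f"{tissue}_{model_type}",
                tissue_group=f"{tissue}_tumor",
            )
            state["gene_corr"][model_type] = df
            _write_df(df, f"genecorr_{model_type}_{tissue}.tsv")
        return

    if stage == "enrich":
        collection = state.get("tissue_sets")
        truth = state.get("truth")
        if collection is None and truth is not None:
            collection = truth.gene_sets()
        if collection is None:
            logger.warning("enrich skipped: no gene-set collection available")
            return
        gene_corr = state.get("gene_corr", {})
        if not gene_corr:
            logger.warning("enrich skipped: no per-gene correlation results")
            return
        for model_type, df in gene_corr.items():
            universe = df.loc[df["class"] != "undefined", "gene_id"]
            for cls in ("correlated_sig", "anticorrelated_sig"):
                query = df.loc[df["class"] == cls, "gene_id"]
                if query.empty:
                    logger.warning("enrich: empty %s class for %s", cls, model_type)
                    continue
                enr = overrepresentation(query, collection, universe, adjust=cfg.adjust)
                _write_df(enr, f"enrichment_{model_type}_{cls}.tsv")
        return

    if stage == "pca":
        n_comp = min(cfg.pca_components, logm.n_genes, logm.n_samples - 1)
        scores, frac = pca_qc(logm, meta, n_components=n_comp)
        _write_df(scores, "pca_scores.tsv", index=True)
        _write_json({"explained_variance_fraction": [float(f) for f in frac]}, "pca_variance.json")
        return
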
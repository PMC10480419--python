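"""Core in-memory containers for expression data, sample metadata and gene sets.

The matrix convention throughout the package is genes x samples: rows are gene
identifiers (Ensembl-style, optionally versioned), columns are sample
identifiers.  Expression values carry an explicit unit tag so that operations
can enforce their input scale (e.g. TPM conversion requires raw counts,
variance ranking requires log2 TPM).
"""
from __future__ import annotations

import dataclasses
import enum
import re
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Unit",
    "DiseaseState",
    "ModelType",
    "ExpressionMatrix",
    "SampleMetadata",
    "GeneSet",
    "GeneSetCollection",
    "GeneSubset",
    "strip_version",
]

_VERSION_RE = re.compile(r"\.\d+$")

#: Relative tolerance on TPM column sums (each column of a TPM matrix must sum
#: to 1e6; all-zero columns from degraded samples are tolerated).
TPM_COLSUM_RTOL = 1e-6


def strip_version(gene_id: str) -> str:
    """Strip a trailing Ensembl version suffix (``ENSG000....5`` -> base ID)."""
    return _VERSION_RE.sub("", gene_id)


class Unit(str, enum.Enum):
    counts = "counts"
    tpm = "tpm"
    log2tpm = "log2tpm"


class DiseaseState(str, enum.Enum):
    tumor = "tumor"
    non_diseased = "non_diseased"


class ModelType(str, enum.Enum):
    cell_line = "cell_line"
    pdx = "pdx"
    tissue = "tissue"


@dataclasses.dataclass
class ExpressionMatrix:
    """A validated genes x samples expression matrix.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with sample IDs as columns.
    unit
        One of ``counts``, ``tpm``, ``log2tpm``.
    gene_lengths
        Per-gene lengths in base pairs; required when ``unit == counts``
        (needed for TPM conversion), optional otherwise.
    """

    values: pd.DataFrame
    unit: Unit
    gene_lengths: pd.Series | None = None
    #: Column sums of a TPM matrix must equal 1e6; gene-restricted views of a
    #: TPM matrix keep the TPM scale but not the sum, so they skip that check.
    validate_tpm_colsums: bool = dataclasses.field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.unit = Unit(self.unit)
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (genes x samples)")
        vals = self.values.to_numpy(dtype=float, copy=False)
        stripped = [strip_version(str(g)) for g in self.values.index]
        dup = pd.Index(stripped)[pd.Index(stripped).duplicated()]
        if len(dup) > 0:
            raise ValueError(
                "duplicate gene IDs after version-stripping: "
                + ", ".join(sorted(set(dup))[:10])
            )
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample IDs")
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite value at gene {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        if self.unit in (Unit.counts, Unit.tpm) and (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative value at gene {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r} (unit={self.unit.value})"
            )
        if self.unit == Unit.tpm and self.validate_tpm_colsums:
            colsums = vals.sum(axis=0)
            nonzero = colsums > 0
            if not np.allclose(colsums[nonzero], 1e6, rtol=TPM_COLSUM_RTOL):
                raise ValueError("TPM columns must each sum to 1e6")
        if self.unit == Unit.counts:
            if self.gene_lengths is None:
                raise ValueError("gene_lengths required when unit=counts")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.values.index)
            if self.gene_lengths.isna().any():
                missing = self.values.index[self.gene_lengths.isna()][:10]
                raise ValueError(
                    "missing gene length for: " + ", ".join(map(str, missing))
                )
            if (self.gene_lengths <= 0).any():
                raise ValueError("gene lengths must be positive")

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def stripped_index(self) -> pd.Index:
        return pd.Index([strip_version(str(g)) for g in self.values.index])

    def restrict_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``gene_ids`` (version-stripped match), preserving the
        requested order for genes present in the matrix."""
        lookup = dict(zip(self.stripped_index(), self.values.index))
        keep = [lookup[strip_version(g)] for g in gene_ids if strip_version(g) in lookup]
        lengths = self.gene_lengths.loc[keep] if self.gene_lengths is not None else None
        return ExpressionMatrix(
            self.values.loc[keep], self.unit, lengths, validate_tpm_colsums=False
        )

    def restrict_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, list(sample_ids)], self.unit, self.gene_lengths
        )

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.unit == other.unit
            and self.values.equals(other.values)
            and (
                (self.gene_lengths is None and other.gene_lengths is None)
                or (
                    self.gene_lengths is not None
                    and other.gene_lengths is not None
                    and self.gene_lengths.equals(other.gene_lengths)
                )
            )
        )


REQUIRED_METADATA_COLUMNS = (
    "sample_id",
    "source",
    "tissue_group",
    "disease_state",
    "model_type",
)
OPTIONAL_METADATA_COLUMNS = ("purity", "excluded", "exclusion_reason")


@dataclasses.dataclass
class SampleMetadata:
    """Per-sample annotations: source cohort, parent tissue group, disease
    state, model type, optional tumor purity and exclusion flag.

    ``model_type == tissue`` marks members of a tissue cohort (the comparison
    targets); ``cell_line``/``pdx`` mark preclinical model samples.  Purity is
    a [0, 1] fraction and may be present only for tumor samples.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()[:10]
            raise ValueError(f"duplicate sample_id in metadata: {dups}")
        df["disease_state"] = df["disease_state"].map(lambda s: DiseaseState(s).value)
        df["model_type"] = df["model_type"].map(lambda s: ModelType(s).value)
        if "purity" not in df.columns:
            df["purity"] = np.nan
        df["purity"] = pd.to_numeric(df["purity"], errors="coerce")
        has_purity = df["purity"].notna()
        if ((df["purity"] < 0) | (df["purity"] > 1)).any():
            raise ValueError("purity values must lie in [0, 1]")
        if (has_purity & (df["disease_state"] != DiseaseState.tumor.value)).any():
            bad = df.loc[
                has_purity & (df["disease_state"] != DiseaseState.tumor.value),
                "sample_id",
            ].tolist()[:10]
            raise ValueError(f"purity given for non-tumor samples: {bad}")
        if "excluded" not in df.columns:
            df["excluded"] = False
        df["excluded"] = df["excluded"].map(
            lambda v: bool(v) if not isinstance(v, str) else v.strip().lower() in ("true", "1", "yes")
        )
        if "exclusion_reason" not in df.columns:
            df["exclusion_reason"] = ""
        df["exclusion_reason"] = df["exclusion_reason"].fillna("")
        self.table = df.reset_index(drop=True)

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Every analyzed sample must have exactly one metadata row."""
        meta_ids = set(self.table["sample_id"])
        missing = [s for s in matrix.sample_ids if s not in meta_ids]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:10]}")

    def select(self, *, include_excluded: bool = False, **criteria) -> pd.DataFrame:
        """Rows matching all ``column=value`` or ``column=[values]`` criteria."""
        df = self.table
        if not include_excluded:
            df = df[~df["excluded"]]
        for col, val in criteria.items():
            if col not in df.columns:
                raise KeyError(f"unknown metadata column {col!r}")
            if isinstance(val, (list, tuple, set, frozenset)):
                df = df[df[col].isin(list(val))]
            else:
                df = df[df[col] == val]
        return df

    def row(self, sample_id: str) -> pd.Series:
        hit = self.table[self.table["sample_id"] == sample_id]
        if hit.empty:
            raise KeyError(f"no metadata for sample {sample_id!r}")
        return hit.iloc[0]


@dataclasses.dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} has no members")
        self.genes = [strip_version(g) for g in self.genes]


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, non-empty member lists,
    members version-stripped."""

    sets: dict[str, GeneSet]

    @classmethod
    def from_dict(cls, d: Mapping[str, Sequence[str]], descriptions: Mapping[str, str] | None = None) -> "GeneSetCollection":
        descriptions = descriptions or {}
        return cls(
            {
                name: GeneSet(name, descriptions.get(name, ""), list(genes))
                for name, genes in d.items()
            }
        )

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclasses.dataclass
class GeneSubset:
    """Named ordered gene list with provenance (how it was constructed)."""

    PROVENANCES = (
        "variance_topk",
        "purity_correlated",
        "tissue_specific_high",
        "tissue_specific_low",
        "custom",
        "full_set",
        "difference",
    )

    name: str
    gene_ids: list[str]
    provenance: str = "custom"
    k: int | None = None
    reference_cohort: str = ""

    def __post_init__(self) -> None:
        if self.provenance not in self.PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        self.gene_ids = [strip_version(g) for g in self.gene_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"gene subset {self.name!r} has duplicate members")
        if self.provenance == "variance_topk" and self.k is not None:
            if len(self.gene_ids) != self.k:
                raise ValueError("variance_topk subset size must equal k")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self) -> Iterable[str]:
        return iter(self.gene_ids)
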
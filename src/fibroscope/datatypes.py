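"""Core domain types shared by every pipeline stage.

The pipeline moves between four substrates: sparse single-cell UMI counts
(:class:`CountMatrix`), per-(sample, cell type) gene detection fractions
(:class:`DetectionProfile`), protein × sample log-intensity tables with
explicit missingness (:class:`ProteinTable`), and per-sample clinical
covariates (a validated :class:`pandas.DataFrame`).  Tabular results
(differential expression, enrichment matrices) are plain DataFrames so they
compose with the usual pandas idiom; container types exist only where there
is an invariant worth enforcing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

DISEASE_LEVELS = ("control", "ILD")
GENDER_LEVELS = ("F", "M")

#: columns every cell-metadata table must carry
CELL_META_COLUMNS = ("sample_id", "cohort_id", "disease_status", "cell_type")

#: columns every sample table must carry
SAMPLE_COLUMNS = (
    "sample_id",
    "cohort_id",
    "disease_status",
    "age",
    "gender",
    "n_cells",
    "total_umi",
)


class ValidationError(ValueError):
    """Raised when an on-disk or in-memory object violates a type invariant."""


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)


@dataclass
class CountMatrix:
    """Sparse cells × genes UMI count matrix plus per-cell metadata.

    ``total_umi``, ``n_genes_detected`` and ``mito_fraction`` in ``cell_meta``
    are always derived from ``counts`` (never trusted from disk); call
    :meth:`recompute_derived` after any manual surgery on ``counts``.
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    cell_meta: pd.DataFrame
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def recompute_derived(self) -> None:
        """Refresh total_umi / n_genes_detected / mito_fraction from counts."""
        counts = self.counts
        total = np.asarray(counts.sum(axis=1)).ravel()
        detected = np.asarray((counts > 0).sum(axis=1)).ravel()
        mito_mask = np.array(
            [str(g).startswith(self.mito_prefix) for g in self.gene_ids]
        )
        if mito_mask.any():
            mito = np.asarray(counts[:, mito_mask].sum(axis=1)).ravel()
        else:
            mito = np.zeros(self.n_cells)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
        self.cell_meta = self.cell_meta.copy()
        self.cell_meta["total_umi"] = total.astype(np.int64)
        self.cell_meta["n_genes_detected"] = detected.astype(np.int64)
        self.cell_meta["mito_fraction"] = frac

    def validate(self) -> "CountMatrix":
        _require(self.counts.shape[0] == len(self.cell_ids), "cell dimension mismatch")
        _require(self.counts.shape[1] == len(self.gene_ids), "gene dimension mismatch")
        for name, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            uniq, counts_ = np.unique(ids, return_counts=True)
            if (counts_ > 1).any():
                dup = uniq[counts_ > 1][0]
                raise ValidationError(f"duplicate {name} id: {dup!r}")
        data = self.counts.data
        _require((data >= 0).all(), "negative counts present")
        if not np.issubdtype(data.dtype, np.integer):
            _require(np.allclose(data, np.round(data)), "non-integer counts present")
            self.counts = self.counts.astype(np.int64)
        _require(len(self.cell_meta) == self.n_cells, "cell_meta length mismatch")
        missing = [c for c in CELL_META_COLUMNS if c not in self.cell_meta.columns]
        _require(not missing, f"cell_meta missing columns: {missing}")
        bad = set(self.cell_meta["disease_status"]) - set(DISEASE_LEVELS)
        _require(not bad, f"unknown disease_status values: {sorted(bad)}")
        self.recompute_derived()
        return self

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        out = CountMatrix(
            counts=self.counts[mask],
            cell_ids=self.cell_ids[mask],
            gene_ids=self.gene_ids,
            cell_meta=self.cell_meta.loc[np.asarray(mask)].reset_index(drop=True)
            if mask.dtype == bool
            else self.cell_meta.iloc[mask].reset_index(drop=True),
            mito_prefix=self.mito_prefix,
        )
        out.recompute_derived()
        return out

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        out = CountMatrix(
            counts=self.counts[:, mask],
            cell_ids=self.cell_ids,
            gene_ids=self.gene_ids[mask],
            cell_meta=self.cell_meta.copy(),
            mito_prefix=self.mito_prefix,
        )
        out.recompute_derived()
        return out

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.counts.shape == other.counts.shape
            and (self.counts != other.counts).nnz == 0
            and np.array_equal(self.cell_ids, other.cell_ids)
            and np.array_equal(self.gene_ids, other.gene_ids)
            and all(
                np.array_equal(
                    self.cell_meta[c].to_numpy(), other.cell_meta[c].to_numpy()
                )
                for c in CELL_META_COLUMNS
            )
        )


@dataclass
class DetectionProfile:
    """(sample, cell type) × gene matrix of gene detection fractions.

    ``values[i, g]`` is the fraction of cells in row *i*'s (sample, cell type)
    group whose count of gene *g* strictly exceeds ``threshold``.  Groups with
    zero cells are simply absent.
    """

    values: np.ndarray  # rows × genes, in [0, 1]
    rows: pd.DataFrame  # columns: sample_id, cell_type, n_cells
    gene_ids: np.ndarray
    threshold: int = 0

    def validate(self) -> "DetectionProfile":
        _require(self.values.ndim == 2, "values must be 2-D")
        _require(len(self.rows) == self.values.shape[0], "row table length mismatch")
        _require(len(self.gene_ids) == self.values.shape[1], "gene dimension mismatch")
        _require(
            bool(((self.values >= 0) & (self.values <= 1)).all()),
            "detection fractions outside [0, 1]",
        )
        _require((self.rows["n_cells"] > 0).all(), "zero-cell rows must be absent")
        return self


@dataclass
class SignatureSet:
    """Named gene sets (cell-type signatures) with optional provenance."""

    signatures: dict[str, list[str]]
    provenance: dict = field(default_factory=dict)

    def validate(self) -> "SignatureSet":
        for name, genes in self.signatures.items():
            _require(len(genes) > 0, f"signature {name!r} is empty")
            _require(
                len(genes) == len(set(genes)),
                f"signature {name!r} contains duplicate genes",
            )
        return self

    def __getitem__(self, name: str) -> list[str]:
        return self.signatures[name]

    def __iter__(self):
        return iter(self.signatures)

    def __len__(self) -> int:
        return len(self.signatures)


@dataclass
class EnrichmentScore:
    """Signed Kolmogorov–Smirnov enrichment of one signature in one context.

    ``signed_score`` is −log10(p) of the two-sample KS test between signature
    and background score distributions, carrying the sign of the enrichment
    direction (positive = signature scores above background).
    """

    signature_name: str
    context_name: str
    signed_score: float
    ks_statistic: float
    p_value: float
    effect_direction: int
    n_signature: int
    n_background: int
    n_missing: int = 0
    undefined: bool = False


@dataclass
class ProteinTable:
    """Proteins × samples intensity matrix with explicit missingness.

    ``intensities`` holds NaN where a protein was not quantified in a sample;
    ``scale_tag`` records which transformations have been applied.
    """

    intensities: pd.DataFrame  # proteins (index) × samples (columns)
    scale_tag: str = "log2"
    imputed_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _require(
            self.scale_tag in ("raw", "log2", "quantile_normalized_scaled"),
            f"unknown scale_tag {self.scale_tag!r}",
        )

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.intensities.isna()

    def validate(self) -> "ProteinTable":
        _require(self.protein_ids.is_unique, "duplicate protein ids")
        _require(self.sample_ids.is_unique, "duplicate sample ids")
        if self.scale_tag == "raw":
            vals = self.intensities.to_numpy()
            _require(
                bool(np.nanmin(vals) >= 0) if np.isfinite(vals).any() else True,
                "negative values in raw-scale table",
            )
        return self


@dataclass
class MetaLungFunction:
    """PCA-derived scalar lung-function score under missing data.

    Oriented so that a larger score means better lung function (the loading on
    the DLCO-like anchor column is positive).
    """

    scores: pd.Series  # per sample
    loadings: pd.Series  # per lung-function column
    explained_variance_ratio: float
    anchor_column: str
    n_iterations: int
    converged: bool


def validate_sample_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the per-sample covariate table invariants and return it."""
    missing = [c for c in SAMPLE_COLUMNS if c not in table.columns]
    _require(not missing, f"sample table missing columns: {missing}")
    _require(table["sample_id"].is_unique, "duplicate sample_id in sample table")
    bad = set(table["disease_status"]) - set(DISEASE_LEVELS)
    _require(not bad, f"unknown disease_status values: {sorted(bad)}")
    bad = set(table["gender"].dropna()) - set(GENDER_LEVELS)
    _require(not bad, f"unknown gender codes: {sorted(bad)}")
    return table


def validate_clinical_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the clinical covariate table invariants and return it."""
    _require("sample_id" in table.columns, "clinical table needs a sample_id column")
    _require(table["sample_id"].is_unique, "duplicate sample_id in clinical table")
    if "gender" in table.columns:
        bad = set(table["gender"].dropna()) - set(GENDER_LEVELS)
        _require(not bad, f"unknown gender codes: {sorted(bad)}")
    return table
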
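"""Readers and writers for the on-disk formats.

Count matrices travel as a matrix-market coordinate triplet (``<prefix>.mtx``)
with ``<prefix>.genes.tsv`` (one gene id per line) and ``<prefix>.cells.tsv``
(TSV with header ``cell_id  sample_id  cohort_id  disease_status  cell_type``)
sidecars.  Protein and clinical tables are TSV/CSV with a header row; missing
values are written as ``NA``.  Signatures are two-column TSV
(``signature  gene``).  All readers re-validate invariants and recompute
derived per-cell statistics rather than trusting them from disk.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp

from .datatypes import (
    CELL_META_COLUMNS,
    CountMatrix,
    ProteinTable,
    SignatureSet,
    ValidationError,
    validate_clinical_table,
    validate_sample_table,
)

logger = logging.getLogger("fibroscope")

NA_VALUES = ("", "NA")


def read_count_matrix(path_prefix: str | Path, mito_prefix: str = "MT-") -> CountMatrix:
    """Load and validate a count matrix from an MTX triplet.

    Derived per-cell fields (total UMI, genes detected, mitochondrial
    fraction) are recomputed from the counts.
    """
    prefix = Path(path_prefix)
    mtx_path = prefix.with_suffix(prefix.suffix + ".mtx")
    genes_path = prefix.with_suffix(prefix.suffix + ".genes.tsv")
    cells_path = prefix.with_suffix(prefix.suffix + ".cells.tsv")
    for p in (mtx_path, genes_path, cells_path):
        if not p.exists():
            raise ValidationError(f"missing count-matrix component: {p}")
    mat = sp.csr_matrix(spio.mmread(mtx_path))
    gene_ids = np.array(
        [line.strip() for line in genes_path.read_text().splitlines() if line.strip()],
        dtype=object,
    )
    cell_meta = pd.read_csv(cells_path, sep="\t", dtype=str, keep_default_na=False)
    cell_meta = cell_meta.replace({"": None})
    missing = [c for c in ("cell_id", *CELL_META_COLUMNS) if c not in cell_meta.columns]
    if missing:
        raise ValidationError(f"cells sidecar missing columns: {missing}")
    if mat.shape != (len(cell_meta), len(gene_ids)):
        raise ValidationError(
            f"dimension mismatch: matrix {mat.shape}, "
            f"{len(cell_meta)} cells / {len(gene_ids)} genes in sidecars"
        )
    cm = CountMatrix(
        counts=mat,
        cell_ids=cell_meta["cell_id"].to_numpy(dtype=object),
        gene_ids=gene_ids,
        cell_meta=cell_meta.drop(columns=["cell_id"]),
        mito_prefix=mito_prefix,
    )
    cm.validate()
    logger.info("read_count_matrix: %d cells × %d genes from %s", *mat.shape, prefix)
    return cm


def write_count_matrix(matrix: CountMatrix, path_prefix: str | Path) -> None:
    """Write a count matrix as an MTX triplet (inverse of read_count_matrix)."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(
        prefix.with_suffix(prefix.suffix + ".mtx"),
        sp.coo_matrix(matrix.counts),
        field="integer",
    )
    prefix.with_suffix(prefix.suffix + ".genes.tsv").write_text(
        "\n".join(str(g) for g in matrix.gene_ids) + "\n"
    )
    meta = matrix.cell_meta.copy()
    meta.insert(0, "cell_id", matrix.cell_ids)
    meta = meta[["cell_id", *CELL_META_COLUMNS]]
    meta.to_csv(
        prefix.with_suffix(prefix.suffix + ".cells.tsv"),
        sep="\t",
        index=False,
        na_rep="NA",
    )


def read_sample_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", na_values=list(NA_VALUES), keep_default_na=False)
    return validate_sample_table(table)


def write_sample_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_protein_table(path: str | Path, scale_tag: str = "log2") -> ProteinTable:
    """Read a proteins × samples intensity TSV; missing cells stay missing."""
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=list(NA_VALUES), keep_default_na=False
    )
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ValidationError(
            f"non-numeric values in intensity columns: {non_numeric}"
        )
    return ProteinTable(intensities=df, scale_tag=scale_tag).validate()


def write_protein_table(table: ProteinTable, path: str | Path) -> None:
    table.intensities.to_csv(path, sep="\t", na_rep="NA")


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read the per-sample clinical covariate CSV (missing values as NA)."""
    df = pd.read_csv(path, na_values=list(NA_VALUES), keep_default_na=False)
    return validate_clinical_table(df)


def write_clinical_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, na_rep="NA")


def read_signature_set(path: str | Path) -> SignatureSet:
    """Read a two-column (signature, gene) TSV into a SignatureSet.

    Duplicate (signature, gene) rows are deduplicated with a warning;
    within-signature gene order follows first appearance.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("signature TSV needs two columns: signature, gene")
    df = df.iloc[:, :2]
    df.columns = ["signature", "gene"]
    n_before = len(df)
    df = df.drop_duplicates()
    if len(df) < n_before:
        logger.warning(
            "read_signature_set: dropped %d duplicate (signature, gene) rows",
            n_before - len(df),
        )
    sigs = {
        name: list(group["gene"]) for name, group in df.groupby("signature", sort=False)
    }
    return SignatureSet(signatures=sigs).validate()


def write_signature_set(sigset: SignatureSet, path: str | Path) -> None:
    rows = [
        {"signature": name, "gene": gene}
        for name in sigset
        for gene in sigset[name]
    ]
    pd.DataFrame(rows, columns=["signature", "gene"]).to_csv(
        path, sep="\t", index=False
    )
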
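"""Cell/gene quality filters, log-normalization, and consensus HVG selection.

The filters follow the standard droplet-QC recipe: drop barcodes with fewer
than 200 detected genes, cells with 4000 or more UMIs (doublet guard, strict
"less than 4000"), and cells with more than 10% mitochondrial counts; keep
genes expressed in at least three cells.  Highly-variable genes are called
per sample (top 4,000 by binned normalized dispersion, ties kept) and then
combined by a two-tier consensus: a gene is HVG if called in ≥ 2 samples; at
the cohort level it must be HVG in ≥ 3 patients of a cohort and then in ≥ 2
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .datatypes import CountMatrix, ValidationError


@dataclass
class QCParams:
    min_genes_per_cell: int = 200
    max_umi_per_cell: int = 4000  # strict: cells with total_umi >= this are dropped
    max_mito_fraction: float = 0.10
    min_cells_per_gene: int = 3
    hvg_top_n: int = 4000
    hvg_min_samples: int = 2
    hvg_min_patients_per_cohort: int = 3
    hvg_min_cohorts: int = 2
    n_dispersion_bins: int = 20
    # provenance passthrough only: ambient-RNA correction cutoff used upstream
    soupx_pcut: float = 0.3

    def validate(self) -> "QCParams":
        for name in (
            "min_genes_per_cell",
            "max_umi_per_cell",
            "min_cells_per_gene",
            "hvg_top_n",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        return self


def filter_cells(matrix: CountMatrix, params: QCParams | None = None):
    """Apply the three per-cell filters; returns (filtered matrix, report).

    A cell failing several criteria is attributed to the first failing one in
    the order genes → UMI → mito, so the report counts sum to the number of
    removed cells.
    """
    params = (params or QCParams()).validate()
    meta = matrix.cell_meta
    fail_genes = meta["n_genes_detected"].to_numpy() < params.min_genes_per_cell
    fail_umi = meta["total_umi"].to_numpy() >= params.max_umi_per_cell
    fail_mito = meta["mito_fraction"].to_numpy() > params.max_mito_fraction
    keep = ~(fail_genes | fail_umi | fail_mito)
    report = {
        "n_in": matrix.n_cells,
        "n_out": int(keep.sum()),
        "removed_low_genes": int(fail_genes.sum()),
        "removed_high_umi": int((fail_umi & ~fail_genes).sum()),
        "removed_high_mito": int((fail_mito & ~fail_genes & ~fail_umi).sum()),
    }
    return matrix.subset_cells(keep), report


def filter_genes(matrix: CountMatrix, params: QCParams | None = None):
    """Keep genes with nonzero counts in at least ``min_cells_per_gene`` cells."""
    params = (params or QCParams()).validate()
    n_cells_expressing = np.asarray((matrix.counts > 0).sum(axis=0)).ravel()
    keep = n_cells_expressing >= params.min_cells_per_gene
    report = {
        "n_in": matrix.n_genes,
        "n_out": int(keep.sum()),
        "removed_low_cells": int((~keep).sum()),
    }
    return matrix.subset_genes(keep), report


def compute_size_factors(matrix: CountMatrix) -> np.ndarray:
    """Per-cell size factors from totals, scaled to mean 1.

    A simple library-size estimator standing in for pooled deconvolution;
    adequate here because downstream statistics work on detection fractions
    or cluster averages, not on fine-grained per-cell magnitudes.
    """
    totals = np.asarray(matrix.counts.sum(axis=1)).ravel().astype(float)
    if (totals == 0).any():
        raise ValidationError("cells with zero total counts have undefined size factors")
    sf = totals / totals.mean()
    return sf


def normalize_log(matrix: CountMatrix, size_factors: np.ndarray | None = None) -> np.ndarray:
    """log1p of size-factor-scaled counts; returns a dense cells × genes array."""
    if size_factors is None:
        size_factors = compute_size_factors(matrix)
    size_factors = np.asarray(size_factors, dtype=float)
    if (size_factors <= 0).any():
        raise ValidationError("size factors must be positive")
    dense = np.asarray(matrix.counts.todense(), dtype=float)
    return np.log1p(dense / size_factors[:, None])


def _normalized_dispersion(logexpr: np.ndarray, n_bins: int) -> np.ndarray:
    """Dispersion (var/mean) z-scored within mean-expression bins.

    The bin count is capped so every bin holds at least 20 genes; a bin with
    too few members would make the within-bin z-score degenerate.
    """
    mean = logexpr.mean(axis=0)
    var = logexpr.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    order = np.argsort(mean, kind="stable")
    n_bins = max(1, min(n_bins, logexpr.shape[1] // 20))
    bins = np.array_split(order, n_bins)
    norm = np.full(logexpr.shape[1], -np.inf)
    for b in bins:
        if len(b) == 0:
            continue
        d = disp[b]
        sd = d.std()
        norm[b] = (d - d.mean()) / sd if sd > 0 else 0.0
    return norm


def hvg_per_sample(
    matrix: CountMatrix, top_n: int = 4000, n_bins: int = 20
) -> set[str]:
    """Top-N genes by binned normalized dispersion for one sample; ties kept."""
    logexpr = normalize_log(matrix)
    score = _normalized_dispersion(logexpr, n_bins)
    if top_n >= len(score):
        return set(map(str, matrix.gene_ids))
    cutoff = np.sort(score)[::-1][top_n - 1]
    keep = score >= cutoff  # keep all ties at the boundary
    return set(map(str, np.asarray(matrix.gene_ids)[keep]))


def consensus_hvg(
    matrix: CountMatrix,
    params: QCParams | None = None,
    level: str = "sample",
) -> list[str]:
    """Two-tier consensus highly-variable-gene selection.

    ``level="sample"``: gene is HVG if in the per-sample top-N in at least
    ``hvg_min_samples`` samples.  ``level="cohort"``: gene is cohort-HVG if
    HVG in at least ``hvg_min_patients_per_cohort`` patients of that cohort,
    and final if cohort-HVG in at least ``hvg_min_cohorts`` cohorts.
    Output order follows the matrix's gene order (permutation-invariant in
    sample order).
    """
    params = (params or QCParams()).validate()
    if level not in ("sample", "cohort"):
        raise ValueError(f"unknown level {level!r}")
    meta = matrix.cell_meta
    sample_ids = meta["sample_id"].unique()
    if len(sample_ids) < 2:
        raise ValidationError("consensus HVG selection needs at least 2 samples")
    per_sample: dict[str, set[str]] = {}
    sample_cohort: dict[str, str] = {}
    for sid in sample_ids:
        mask = (meta["sample_id"] == sid).to_numpy()
        sub = matrix.subset_cells(mask)
        per_sample[sid] = hvg_per_sample(sub, params.hvg_top_n, params.n_dispersion_bins)
        sample_cohort[sid] = str(meta.loc[mask, "cohort_id"].iloc[0])

    gene_order = [str(g) for g in matrix.gene_ids]
    if level == "sample":
        counts = {g: 0 for g in gene_order}
        for sid in sample_ids:
            for g in per_sample[sid]:
                counts[g] += 1
        return [g for g in gene_order if counts[g] >= params.hvg_min_samples]

    cohorts = sorted(set(sample_cohort.values()))
    cohort_hvg: dict[str, set[str]] = {}
    for cohort in cohorts:
        members = [s for s in sample_ids if sample_cohort[s] == cohort]
        counts = {}
        for sid in members:
            for g in per_sample[sid]:
                counts[g] = counts.get(g, 0) + 1
        cohort_hvg[cohort] = {
            g for g, c in counts.items() if c >= params.hvg_min_patients_per_cohort
        }
    return [
        g
        for g in gene_order
        if sum(g in cohort_hvg[c] for c in cohorts) >= params.hvg_min_cohorts
    ]
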
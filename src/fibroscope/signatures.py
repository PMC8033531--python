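"""Cell-type signature derivation and signed-KS enrichment scoring.

Signatures are sets of genes with significant cell-type-specific expression,
derived here by a one-vs-rest detection regression.  Enrichment of a
signature in a ranked list (fold changes, correlation coefficients, or group
mean z-scores) is scored with a two-sample Kolmogorov–Smirnov test between
the signature members' scores and all background items; the signed score is
−log10(p) carrying the sign of the enrichment direction, so positive values
mean the signature sits high in the ranking and negative values mean
depletion.  A matrix of such scores across contexts acts as a simple
cell-type deconvolution of bulk measurements.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    CountMatrix,
    EnrichmentScore,
    ProteinTable,
    SignatureSet,
    ValidationError,
)
from .detection import adjust_pvalues, detection_profile, ols_outcome_test

_P_FLOOR = 1e-300


def derive_signatures(
    matrix: CountMatrix,
    sample_table: pd.DataFrame,
    alpha: float = 0.05,
    min_genes: int = 5,
    max_genes: int = 100,
    detect_threshold: int = 0,
) -> SignatureSet:
    """One-vs-rest marker signatures from detection regressions.

    For each cell type, the sqrt detection probability is regressed on an
    indicator of that type (vs all other types) with the usual sample
    covariates; genes with BH-adjusted p < alpha and positive coefficient are
    its markers, capped at ``max_genes`` by |t|.  Cell types yielding fewer
    than ``min_genes`` markers are omitted.
    """
    profile = detection_profile(matrix, detect_threshold=detect_threshold)
    st = sample_table.set_index("sample_id")
    rows = profile.rows
    signatures: dict[str, list[str]] = {}
    dropped: list[str] = []
    for cell_type in sorted(rows["cell_type"].unique()):
        design = rows.copy()
        for col in ("cohort_id", "age", "gender", "total_umi"):
            design[col] = st.loc[design["sample_id"], col].to_numpy()
        design["n_cells_sample"] = st.loc[design["sample_id"], "n_cells"].to_numpy()
        onevrest = (design["cell_type"] == cell_type).to_numpy(float)
        cols = {
            "intercept": np.ones(len(design)),
            "outcome": onevrest,
            "log10_total_umi": np.log10(design["total_umi"].to_numpy(float)),
            "log10_n_cells": np.log10(design["n_cells_sample"].to_numpy(float)),
            "age": design["age"].to_numpy(float),
            "gender": (design["gender"] == "M").to_numpy(float),
        }
        for c in sorted(design["cohort_id"].unique())[1:]:
            cols[f"cohort_{c}"] = (design["cohort_id"] == c).to_numpy(float)
        X = np.column_stack(list(cols.values()))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            dropped.append(cell_type)
            continue
        coef, t, p = ols_outcome_test(X, np.sqrt(profile.values), 1)
        table = adjust_pvalues(
            pd.DataFrame(
                {"gene": profile.gene_ids, "coefficient": coef, "t_value": t, "p_value": p}
            ),
            within=None,
        )
        hits = table[(table["adjusted_p"] < alpha) & (table["coefficient"] > 0)]
        hits = hits.reindex(hits["t_value"].abs().sort_values(ascending=False).index)
        genes = [str(g) for g in hits["gene"].head(max_genes)]
        if len(genes) < min_genes:
            dropped.append(cell_type)
            continue
        signatures[cell_type] = genes
    return SignatureSet(
        signatures=signatures,
        provenance={
            "alpha": alpha,
            "max_genes": max_genes,
            "rule": "one-vs-rest detection regression, adjusted p < alpha, coef > 0",
            "omitted_cell_types": dropped,
        },
    ).validate()


def ks_signature_score(
    signature_genes: list[str],
    ranked_list: pd.Series,
    signature_name: str = "",
    context_name: str = "",
    method: str = "auto",
    small_signature: int = 20,
) -> EnrichmentScore:
    """Signed −log10 KS p-value of a signature in a ranked list.

    ``ranked_list`` maps item ids to scores.  The two-sample KS test compares
    signature members' scores against all other items; the sign is the sign
    of the difference in mean scores (positive = enrichment).  Signature
    items missing from the list are dropped and counted.  ``method='auto'``
    uses the exact two-sample p-value for signatures smaller than
    ``small_signature`` members and the asymptotic p otherwise.
    """
    if not ranked_list.index.is_unique:
        raise ValidationError("ranked list has duplicate item ids")
    scores = ranked_list.astype(float)
    if not np.isfinite(scores.to_numpy()).all():
        raise ValidationError("ranked list contains non-finite scores")
    members = pd.Index(pd.unique(pd.Series(signature_genes, dtype=object)))
    in_list = members.intersection(scores.index)
    n_missing = len(members) - len(in_list)
    if len(in_list) == 0 or len(in_list) == len(scores):
        return EnrichmentScore(
            signature_name=signature_name,
            context_name=context_name,
            signed_score=np.nan,
            ks_statistic=np.nan,
            p_value=np.nan,
            effect_direction=0,
            n_signature=len(in_list),
            n_background=len(scores) - len(in_list),
            n_missing=n_missing,
            undefined=True,
        )
    sig = scores.loc[in_list].to_numpy()
    bg = scores.drop(in_list).to_numpy()
    if method == "auto":
        method = "exact" if len(sig) < small_signature else "asymp"
    ks = stats.ks_2samp(sig, bg, method=method)
    direction = int(np.sign(sig.mean() - bg.mean()))
    signed = -np.log10(max(ks.pvalue, _P_FLOOR)) * direction
    return EnrichmentScore(
        signature_name=signature_name,
        context_name=context_name,
        signed_score=float(signed),
        ks_statistic=float(ks.statistic),
        p_value=float(ks.pvalue),
        effect_direction=direction,
        n_signature=len(sig),
        n_background=len(bg),
        n_missing=n_missing,
    )


def deconvolution_scores(
    ranked_lists: dict[str, pd.Series],
    signature_set: SignatureSet,
    method: str = "auto",
) -> pd.DataFrame:
    """Signature × context table of signed KS scores (long format).

    One row per (signature, context); undefined cells (empty intersection)
    are flagged rather than dropped.  The result is invariant to the order of
    signatures and contexts.
    """
    rows = []
    for sig_name in sorted(signature_set.signatures):
        for context in sorted(ranked_lists):
            es = ks_signature_score(
                signature_set[sig_name],
                ranked_lists[context],
                signature_name=sig_name,
                context_name=context,
                method=method,
            )
            rows.append(
                {
                    "signature": es.signature_name,
                    "context": es.context_name,
                    "ks_statistic": es.ks_statistic,
                    "p_value": es.p_value,
                    "signed_score": es.signed_score,
                    "effect_direction": es.effect_direction,
                    "n_signature": es.n_signature,
                    "n_missing": es.n_missing,
                    "undefined": es.undefined,
                }
            )
    return pd.DataFrame(rows)


def pivot_scores(long_scores: pd.DataFrame) -> pd.DataFrame:
    """Signature × context matrix of signed scores from the long table."""
    return long_scores.pivot(index="signature", columns="context", values="signed_score")


def group_zscore_ranked_lists(
    protein_table: ProteinTable, groups: pd.Series
) -> dict[str, pd.Series]:
    """Per-group mean intensity z-scores, one ranked list per group.

    Each protein is z-scored across all samples (observed values only), then
    averaged within each diagnosis group — the ranked input for scoring how
    cell-type signatures shift between patient groups.
    """
    intens = protein_table.intensities
    groups = groups.reindex(intens.columns)
    if groups.isna().any():
        missing = list(intens.columns[groups.isna()])
        raise ValidationError(f"samples without group label: {missing}")
    z = intens.sub(intens.mean(axis=1), axis=0).div(
        intens.std(axis=1).replace(0, np.nan), axis=0
    )
    out = {}
    for g in sorted(groups.unique()):
        cols = intens.columns[groups == g]
        mean_z = z[cols].mean(axis=1).dropna()
        out[str(g)] = mean_z
    return out
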
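"""Body-fluid proteome and clinical statistics.

Covers the proteomic arm of the study: abundance filters (proteins
quantified in at least 20 patients; high-CV selection), pairwise-complete
protein–clinical Pearson correlations, a PCA-derived "meta lung function"
score robust to missing clinical values (iterative-PCA imputation), random
forest-style iterative imputation of protein intensities, per-protein
multivariate regression of meta lung function on protein abundance with age
and gender as covariates, and an epithelial-lining-fluid (ELF) vs
tissue-leakage enrichment score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import BayesianRidge

from .datatypes import MetaLungFunction, ProteinTable, ValidationError
from .detection import adjust_pvalues, ols_outcome_test


def filter_min_patients(table: ProteinTable, min_n: int = 20) -> ProteinTable:
    """Keep proteins quantified (non-missing) in at least ``min_n`` samples."""
    n_obs = table.intensities.notna().sum(axis=1)
    keep = n_obs >= min_n
    return ProteinTable(
        intensities=table.intensities.loc[keep], scale_tag=table.scale_tag
    ).validate()


def cv_filter(
    table: ProteinTable, cv_threshold: float | None = None
) -> tuple[list[str], pd.Series]:
    """Proteins whose coefficient of variation across patients exceeds a cutoff.

    CV = sd/mean over observed values on the raw intensity scale (log2 tables
    are exponentiated first).  With ``cv_threshold=None`` the cutoff is the
    upper quartile of CVs.  Proteins with zero mean are skipped (NaN CV).
    Returns (selected protein ids, per-protein CV series).
    """
    intens = table.intensities
    if table.scale_tag == "log2":
        intens = np.power(2.0, intens)
    elif table.scale_tag != "raw":
        raise ValidationError("cv_filter needs raw or log2 intensities")
    mean = intens.mean(axis=1)
    sd = intens.std(axis=1)
    cv = sd / mean.where(mean != 0)
    if cv_threshold is None:
        cv_threshold = float(cv.quantile(0.75))
    selected = list(cv.index[cv > cv_threshold])
    return selected, cv


def protein_clinical_correlation(
    table: ProteinTable,
    clinical: pd.DataFrame,
    parameters: list[str] | None = None,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation of proteins with clinical columns.

    Returns a long DataFrame (protein, parameter, r, p_value, n); cells with
    fewer than ``min_pairs`` complete pairs or a constant vector are flagged
    with ``undefined=True``.
    """
    clin = clinical.set_index("sample_id")
    shared = table.sample_ids.intersection(clin.index)
    if len(shared) == 0:
        raise ValidationError("no shared samples between protein and clinical tables")
    if parameters is None:
        parameters = [
            c
            for c in clin.columns
            if pd.api.types.is_numeric_dtype(clin[c]) and c not in ("age",)
        ]
    intens = table.intensities[shared]
    rows = []
    for param in parameters:
        y = clin.loc[shared, param].astype(float).to_numpy()
        for protein in intens.index:
            x = intens.loc[protein].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            undefined = n < min_pairs or np.std(x[ok]) == 0 or np.std(y[ok]) == 0
            if undefined:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x[ok], y[ok])
            rows.append(
                {
                    "protein": protein,
                    "parameter": param,
                    "r": float(r) if not undefined else np.nan,
                    "p_value": float(p) if not undefined else np.nan,
                    "n": n,
                    "undefined": undefined,
                }
            )
    return pd.DataFrame(rows)


def iterative_pca_impute(
    X: np.ndarray,
    n_components: int = 1,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[np.ndarray, int, bool]:
    """EM-style PCA completion of a matrix with NaN cells.

    Alternates a rank-``n_components`` SVD reconstruction of the
    column-standardized matrix with refreshing of the column means/scales;
    missing cells start at the column mean and converge when their largest
    change drops below ``tol``.  Returns (completed matrix, iterations,
    converged flag).  A matrix whose complete version is exactly low-rank is
    recovered exactly (up to ``tol``).
    """
    raw = np.asarray(X, dtype=float)
    mask = np.isnan(raw)
    work = raw.copy()
    if not mask.any():
        return work, 0, True
    col_mean = np.nanmean(raw, axis=0)
    work[mask] = np.take(col_mean, np.where(mask)[1])
    converged = False
    n_iter = 0
    delta = np.inf
    for n_iter in range(1, max_iter + 1):
        m = work.mean(axis=0)
        s = work.std(axis=0, ddof=0)
        s = np.where(s > 0, s, 1.0)
        Z = (work - m) / s
        U, D, Vt = np.linalg.svd(Z, full_matrices=False)
        k = min(n_components, len(D))
        recon = (U[:, :k] * D[:k]) @ Vt[:k]
        filled = recon * s + m
        delta = np.max(np.abs(filled[mask] - work[mask]))
        work[mask] = filled[mask]
        if delta < tol:
            converged = True
            break
    if not converged:
        raise ValidationError(
            f"iterative PCA imputation did not converge in {max_iter} iterations "
            f"(last change {delta:.3g})"
        )
    return work, n_iter, converged


def meta_lung_function(
    clinical: pd.DataFrame,
    lungfn_columns: list[str],
    anchor_column: str | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> MetaLungFunction:
    """PCA-derived scalar lung-function score under missing data.

    Missing cells are filled by iterative PCA (EM): alternate a rank-1 SVD
    reconstruction of the column-standardized table with refreshing of the
    column means/scales, until imputed values change by less than ``tol``.
    The score is the first principal component of the completed standardized
    table, oriented so the loading on the anchor column (default: the first
    DLCO-like column, else the first column) is positive — larger score means
    better lung function.  On a complete table this reduces exactly to PC1.
    """
    missing_cols = [c for c in lungfn_columns if c not in clinical.columns]
    if missing_cols:
        raise ValidationError(f"lung-function columns absent: {missing_cols}")
    if len(lungfn_columns) < 2:
        raise ValidationError("need at least 2 lung-function columns")
    X = clinical.set_index("sample_id")[lungfn_columns].astype(float)
    frac_missing = X.isna().mean()
    if (frac_missing >= 0.5).any():
        bad = list(frac_missing.index[frac_missing >= 0.5])
        raise ValidationError(f"columns with >= 50% missingness: {bad}")
    if anchor_column is None:
        dlco = [c for c in lungfn_columns if "DLCO" in c.upper()]
        anchor_column = dlco[0] if dlco else lungfn_columns[0]

    work, n_iter, converged = iterative_pca_impute(
        X.to_numpy(), n_components=1, tol=tol, max_iter=max_iter
    )
    m = work.mean(axis=0)
    s = work.std(axis=0, ddof=0)
    s = np.where(s > 0, s, 1.0)
    Z = (work - m) / s
    U, D, Vt = np.linalg.svd(Z, full_matrices=False)
    loading = Vt[0]
    score = Z @ loading
    anchor_idx = lungfn_columns.index(anchor_column)
    if loading[anchor_idx] < 0:
        loading, score = -loading, -score
    evr = float(D[0] ** 2 / (D**2).sum())
    return MetaLungFunction(
        scores=pd.Series(score, index=X.index, name="meta_lung_function"),
        loadings=pd.Series(loading, index=lungfn_columns, name="loading"),
        explained_variance_ratio=evr,
        anchor_column=anchor_column,
        n_iterations=n_iter,
        converged=converged,
    )


def impute_proteins(
    table: ProteinTable,
    estimator: str = "forest",
    n_estimators: int = 10,
    max_iter: int = 5,
    seed: int = 0,
) -> ProteinTable:
    """Iterative imputation of missing intensities (missForest-style).

    Each protein with missing values is regressed on all other proteins and
    the predictions fill its gaps, sweeping proteins repeatedly until the
    imputed values stabilize.  ``estimator='forest'`` uses random-forest
    regressors (nonparametric, the default); ``'ridge'`` uses Bayesian ridge
    (much faster, for large screens).  Proteins with fewer than 3 observed
    values are left at their median and flagged.  Deterministic under a fixed
    seed.  The returned table keeps the mask of originally missing cells.
    """
    intens = table.intensities
    mask = intens.isna()
    if not mask.to_numpy().any():
        return ProteinTable(
            intensities=intens.copy(), scale_tag=table.scale_tag, imputed_mask=mask
        )
    n_obs = intens.notna().sum(axis=1)
    sparse_proteins = n_obs < 3
    X = intens.T.to_numpy(dtype=float)  # samples × proteins
    if estimator == "forest":
        est = RandomForestRegressor(
            n_estimators=n_estimators, n_jobs=1, random_state=seed
        )
    elif estimator == "ridge":
        est = BayesianRidge()
    else:
        raise ValidationError(f"unknown estimator {estimator!r}")
    imputer = IterativeImputer(
        estimator=est,
        max_iter=max_iter,
        random_state=seed,
        sample_posterior=False,
        keep_empty_features=True,
    )
    filled = imputer.fit_transform(X).T
    out = pd.DataFrame(filled, index=intens.index, columns=intens.columns)
    # proteins with almost no observations are not imputable by regression
    for protein in intens.index[sparse_proteins]:
        med = intens.loc[protein].median()
        if np.isnan(med):
            med = float(np.nanmedian(intens.to_numpy()))
        out.loc[protein] = intens.loc[protein].fillna(med)
    return ProteinTable(
        intensities=out, scale_tag=table.scale_tag, imputed_mask=mask
    ).validate()


def lungfunction_regression(
    table: ProteinTable,
    meta_lf: pd.Series,
    age: pd.Series,
    gender: pd.Series,
) -> pd.DataFrame:
    """Per-protein OLS of meta lung function on protein + age + gender.

    Inputs must be complete (impute first).  Returns a DataFrame with the
    protein coefficient, t, two-sided p, and BH-adjusted p across proteins;
    collinear proteins are flagged instead of fit.
    """
    samples = table.sample_ids
    y = meta_lf.reindex(samples).to_numpy(dtype=float)
    a = age.reindex(samples).to_numpy(dtype=float)
    g = pd.Series(gender).reindex(samples).map({"F": 0.0, "M": 1.0}).to_numpy(dtype=float)
    if np.isnan(y).any() or np.isnan(a).any() or np.isnan(g).any():
        raise ValidationError("meta_lf, age and gender must be complete")
    if table.intensities.isna().to_numpy().any():
        raise ValidationError("protein table must be imputed before regression")
    rows = []
    base = np.column_stack([np.ones(len(samples)), np.zeros(len(samples)), a, g])
    for protein in table.protein_ids:
        x = table.intensities.loc[protein].to_numpy(dtype=float)
        X = base.copy()
        X[:, 1] = x
        if np.linalg.matrix_rank(X) < X.shape[1]:
            rows.append(
                {
                    "protein": protein,
                    "coefficient": np.nan,
                    "t_value": np.nan,
                    "p_value": np.nan,
                    "flagged": True,
                }
            )
            continue
        coef, t, p = ols_outcome_test(X, y[:, None], 1)
        rows.append(
            {
                "protein": protein,
                "coefficient": float(coef[0]),
                "t_value": float(t[0]),
                "p_value": float(p[0]),
                "flagged": False,
            }
        )
    result = pd.DataFrame(rows)
    return adjust_pvalues(result, within=None)


def relative_abundance(table: ProteinTable) -> pd.DataFrame:
    """Per-sample fractional intensity (columns sum to 1 over observed values)."""
    intens = table.intensities
    if table.scale_tag == "log2":
        intens = np.power(2.0, intens)
    totals = intens.sum(axis=0, skipna=True)
    return intens.div(totals, axis=1)


def elf_score(
    balf_table: ProteinTable, tissue_table: ProteinTable
) -> pd.DataFrame:
    """Epithelial-lining-fluid vs tissue-leakage enrichment per protein.

    Both tables are converted to per-sample relative abundances; the raw
    score is log2(median BALF rel. abundance) − log2(median tissue rel.
    abundance), z-scored over proteins present in both compartments.  Higher
    = more ELF-like (locally secreted); the score is antisymmetric under
    swapping compartments.  Proteins absent from one compartment get a
    half-minimum substitution and are flagged.
    """
    balf_rel = relative_abundance(balf_table)
    tissue_rel = relative_abundance(tissue_table)
    proteins = balf_rel.index.union(tissue_rel.index)
    med_b = balf_rel.median(axis=1).reindex(proteins)
    med_t = tissue_rel.median(axis=1).reindex(proteins)
    flagged = med_b.isna() | med_t.isna() | (med_b <= 0) | (med_t <= 0)
    half_min_b = med_b[med_b > 0].min() / 2
    half_min_t = med_t[med_t > 0].min() / 2
    med_b = med_b.fillna(half_min_b).clip(lower=half_min_b)
    med_t = med_t.fillna(half_min_t).clip(lower=half_min_t)
    raw = np.log2(med_b) - np.log2(med_t)
    z = (raw - raw.mean()) / raw.std(ddof=0)
    return pd.DataFrame(
        {"raw_score": raw, "elf_zscore": z, "flagged": flagged}
    ).rename_axis("protein")


def top_abundant_mass_fraction(
    table: ProteinTable, reference: ProteinTable, n_top: int = 100
) -> pd.Series:
    """Per-sample mass fraction contributed by the reference's top-n proteins.

    The n most abundant proteins of a reference compartment (e.g. plasma,
    by median relative abundance) are looked up in ``table`` and their summed
    relative abundance per sample is returned — a plasma-leakage diagnostic.
    """
    ref_rank = relative_abundance(reference).median(axis=1).sort_values(ascending=False)
    top = ref_rank.head(n_top).index
    rel = relative_abundance(table)
    present = rel.index.intersection(top)
    return rel.loc[present].sum(axis=0).rename("top_reference_mass_fraction")
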
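"""Detection-probability differential expression.

Disease status varies at the sample level, not the cell level, so instead of
cell-level tests the pipeline models, for every (sample, cell type) group,
the fraction of cells in which each gene is detected.  These detection
probabilities are square-root transformed (they live in [0, 1]) and regressed
on the outcome of interest (ILD status or gender) with sample-level
covariates: log10 total UMI count, log10 number of cells, study-cohort
indicators, age, and gender.  The t- and p-values of the outcome coefficient
are the DE statistics; p-values are Benjamini–Hochberg adjusted within each
cell type.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .datatypes import CountMatrix, DetectionProfile, ValidationError

_T_CAP = 1e6  # reported |t| when the fit is exact (zero residual variance)


def ols_outcome_test(
    X: np.ndarray, Y: np.ndarray, coef_index: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS of each column of ``Y`` on the shared design ``X``.

    Returns (coefficients, t-values, two-sided p-values) for the column
    ``coef_index`` of ``X``.  Columns of ``Y`` with an exact fit get t = 0 and
    p = 1 when the coefficient is zero (constant response), otherwise a capped
    t with p = 0.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValidationError(f"need more rows ({n}) than design columns ({k})")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    coef = beta[coef_index]
    var_unit = xtx_inv[coef_index, coef_index]
    se = np.sqrt(np.maximum(sigma2 * var_unit, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / np.where(se > 0, se, 1.0), 0.0)
    exact = sigma2 <= np.finfo(float).eps * np.abs(Y).max(initial=1.0) ** 2
    constant = exact & (np.abs(coef) <= 1e-12)
    t = np.where(exact & ~constant, np.sign(coef) * _T_CAP, t)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    coef = np.where(constant, 0.0, coef)
    t = np.where(constant, 0.0, t)
    p = np.where(constant, 1.0, p)
    return coef, t, p


def detection_profile(
    matrix: CountMatrix,
    detect_threshold: int = 0,
    min_cells: int = 1,
) -> DetectionProfile:
    """Per-(sample, cell type) fraction of cells with count > threshold.

    ``detect_threshold=0`` reads detection as count ≥ 1 (the default);
    ``detect_threshold=1`` as count > 1.  Groups with fewer than ``min_cells``
    cells are omitted rather than reported as NaN.
    """
    if detect_threshold not in (0, 1):
        raise ValidationError("detect_threshold must be 0 or 1")
    meta = matrix.cell_meta
    if meta["cell_type"].isna().any():
        bad = meta.index[meta["cell_type"].isna()][0]
        raise ValidationError(f"cell at position {bad} has no cell_type label")
    groups = meta.groupby(["sample_id", "cell_type"], sort=True, observed=True).indices
    detected = (matrix.counts > detect_threshold).astype(np.float64)
    rows, values = [], []
    for (sample_id, cell_type), idx in groups.items():
        if len(idx) < min_cells:
            continue
        frac = np.clip(np.asarray(detected[idx].mean(axis=0)).ravel(), 0.0, 1.0)
        rows.append(
            {"sample_id": sample_id, "cell_type": cell_type, "n_cells": len(idx)}
        )
        values.append(frac)
    if not rows:
        raise ValidationError("no (sample, cell type) group met the min_cells floor")
    profile = DetectionProfile(
        values=np.vstack(values),
        rows=pd.DataFrame(rows),
        gene_ids=np.asarray(matrix.gene_ids, dtype=object),
        threshold=detect_threshold,
    )
    return profile.validate()


def _build_design(
    rows: pd.DataFrame, outcome: str
) -> tuple[np.ndarray, list[str], int]:
    """Design matrix: intercept + outcome + sample covariates (minus outcome)."""
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(rows))}
    if outcome == "disease_status":
        cols["outcome"] = (rows["disease_status"] == "ILD").to_numpy(float)
    elif outcome == "gender":
        cols["outcome"] = (rows["gender"] == "M").to_numpy(float)
    else:
        raise ValidationError(f"unknown outcome {outcome!r}")
    cols["log10_total_umi"] = np.log10(rows["total_umi"].to_numpy(float))
    cols["log10_n_cells"] = np.log10(rows["n_cells_sample"].to_numpy(float))
    cohorts = sorted(rows["cohort_id"].unique())
    for c in cohorts[1:]:  # first cohort is the reference level
        cols[f"cohort_{c}"] = (rows["cohort_id"] == c).to_numpy(float)
    cols["age"] = rows["age"].to_numpy(float)
    if outcome != "gender":
        cols["gender"] = (rows["gender"] == "M").to_numpy(float)
    # constant covariates (e.g. equal cell counts) carry no information and
    # would only make the design collinear with the intercept
    for name in list(cols):
        if name not in ("intercept", "outcome") and np.ptp(cols[name]) == 0:
            del cols[name]
    X = np.column_stack(list(cols.values()))
    return X, list(cols.keys()), list(cols.keys()).index("outcome")


def fit_detection_regression(
    profile: DetectionProfile,
    sample_table: pd.DataFrame,
    outcome: str = "disease_status",
    min_samples_per_level: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Covariate-adjusted OLS of sqrt detection probability, per cell type.

    Returns a long DataFrame (cell_type, gene, coefficient, t_value, p_value,
    n_samples_used) for the outcome coefficient, plus a report naming skipped
    cell types.  Cell types whose design is rank-deficient or that lack
    ``min_samples_per_level`` samples per outcome level are skipped.
    """
    st = sample_table.set_index("sample_id")
    rows = profile.rows.copy()
    unknown = set(rows["sample_id"]) - set(st.index)
    if unknown:
        raise ValidationError(f"profile samples missing from sample table: {sorted(unknown)}")
    for col in ("cohort_id", "disease_status", "age", "gender", "total_umi"):
        rows[col] = st.loc[rows["sample_id"], col].to_numpy()
    rows["n_cells_sample"] = st.loc[rows["sample_id"], "n_cells"].to_numpy()

    results = []
    report: dict = {"skipped": {}}
    for cell_type, sub in rows.groupby("cell_type", sort=True):
        idx = sub.index.to_numpy()
        X, names, coef_idx = _build_design(sub, outcome)
        levels = X[:, coef_idx]
        n0, n1 = int((levels == 0).sum()), int((levels == 1).sum())
        if min(n0, n1) < min_samples_per_level:
            report["skipped"][cell_type] = (
                f"only {min(n0, n1)} samples in the smaller outcome level"
            )
            continue
        if X.shape[0] <= X.shape[1] or np.linalg.matrix_rank(X) < X.shape[1]:
            report["skipped"][cell_type] = "rank-deficient design (collinear covariates)"
            continue
        Y = np.sqrt(profile.values[idx])
        coef, t, p = ols_outcome_test(X, Y, coef_idx)
        results.append(
            pd.DataFrame(
                {
                    "cell_type": cell_type,
                    "gene": profile.gene_ids,
                    "coefficient": coef,
                    "t_value": t,
                    "p_value": p,
                    "n_samples_used": len(idx),
                }
            )
        )
    if not results:
        raise ValidationError(f"no cell type could be fit: {report['skipped']}")
    de = pd.concat(results, ignore_index=True)
    return de, report


def adjust_pvalues(
    de_result: pd.DataFrame, method: str = "BH", within: str | None = "cell_type"
) -> pd.DataFrame:
    """Benjamini–Hochberg adjustment, by default within each cell type."""
    if method not in ("BH", "BY"):
        raise ValidationError(f"unknown adjustment method {method!r}")
    out = de_result.copy()
    scipy_method = {"BH": "bh", "BY": "by"}[method]

    def _adjust(p: pd.Series) -> pd.Series:
        adj = pd.Series(np.nan, index=p.index)
        ok = p.notna()
        if ok.any():
            adj[ok] = stats.false_discovery_control(p[ok].to_numpy(), method=scipy_method)
        return adj

    if within is not None and within in out.columns:
        out["adjusted_p"] = (
            out.groupby(within, group_keys=False)["p_value"].apply(_adjust)
        )
    else:
        out["adjusted_p"] = _adjust(out["p_value"])
    return out


def crosscohort_concordance(
    results: dict[str, pd.DataFrame], min_shared: int = 3
) -> pd.DataFrame:
    """Pearson correlation of t-values between independently fit runs.

    ``results`` maps run name (e.g. cohort) to a DE table; correlations are
    computed over (cell_type, gene) pairs tested in both runs.  Pairs with
    fewer than ``min_shared`` shared genes get NaN.
    """
    names = list(results)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        ta = results[a].set_index(["cell_type", "gene"])["t_value"]
        for b in names[i + 1 :]:
            tb = results[b].set_index(["cell_type", "gene"])["t_value"]
            shared = ta.index.intersection(tb.index)
            if len(shared) < min_shared:
                r = np.nan
            else:
                x, y = ta.loc[shared].to_numpy(), tb.loc[shared].to_numpy()
                ok = np.isfinite(x) & np.isfinite(y)
                r = (
                    float(np.corrcoef(x[ok], y[ok])[0, 1])
                    if ok.sum() >= min_shared
                    else np.nan
                )
            mat.loc[a, b] = mat.loc[b, a] = r
    return mat
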
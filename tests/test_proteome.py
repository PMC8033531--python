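import numpy as np
import pandas as pd
import pytest

import fibroscope as fs
from fibroscope import ProteinTable
from fibroscope.proteome import relative_abundance, top_abundant_mass_fraction


def _table(values, scale="log2", proteins=None, samples=None):
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=proteins or [f"P{i}" for i in range(values.shape[0])],
        columns=samples or [f"s{i}" for i in range(values.shape[1])],
    )
    return ProteinTable(intensities=df, scale_tag=scale)


@pytest.mark.parametrize("n_obs, kept", [(19, False), (20, True)])
def test_min_patients_filter_boundary(n_obs, kept):
    row = np.full(25, np.nan)
    row[:n_obs] = 1.0
    table = _table(np.vstack([row, np.ones(25)]))
    out = fs.filter_min_patients(table, min_n=20)
    assert ("P0" in out.protein_ids) is kept
    assert "P1" in out.protein_ids


def test_min_patients_filter_identity_on_complete_table():
    table = _table(np.random.default_rng(0).normal(20, 1, (5, 25)))
    out = fs.filter_min_patients(table)
    pd.testing.assert_frame_equal(out.intensities, table.intensities)


def test_cv_hand_arithmetic():
    table = _table([[1, 2, 3], [5, 5, 5]], scale="raw")
    selected, cv = fs.cv_filter(table, cv_threshold=0.49)
    assert cv["P0"] == pytest.approx(0.5)  # sd/mean of {1,2,3}
    assert cv["P1"] == 0.0
    assert selected == ["P0"]
    none_sel, _ = fs.cv_filter(table, cv_threshold=0.51)
    assert none_sel == []


def test_cv_filter_recovers_planted_high_variance_proteins():
    rng = np.random.default_rng(1)
    quiet = rng.normal(100, 2, size=(40, 30))
    loud = rng.normal(100, 40, size=(10, 30)).clip(min=1)
    table = _table(np.vstack([quiet, loud]), scale="raw")
    selected, _ = fs.cv_filter(table, cv_threshold=0.1)
    planted = {f"P{i}" for i in range(40, 50)}
    assert planted <= set(selected)


def test_protein_equal_to_parameter_has_r_one():
    rng = np.random.default_rng(2)
    vals = rng.normal(50, 10, 20)
    table = _table(vals[None, :])
    clin = pd.DataFrame({"sample_id": table.sample_ids, "DLCO": vals})
    out = fs.protein_clinical_correlation(table, clin, parameters=["DLCO"])
    assert out["r"].iloc[0] == pytest.approx(1.0)


def test_correlation_flags_underpowered_and_constant_cells():
    vals = np.array([[1.0, 2.0, 3.0, np.nan] * 3, [5.0] * 12])
    table = _table(vals)
    clin = pd.DataFrame(
        {"sample_id": table.sample_ids, "param": np.arange(12, dtype=float)}
    )
    out = fs.protein_clinical_correlation(table, clin, parameters=["param"], min_pairs=10)
    assert bool(out.loc[out["protein"] == "P0", "undefined"].iloc[0])  # n=9 < 10
    assert bool(out.loc[out["protein"] == "P1", "undefined"].iloc[0])  # constant


def _clinical_from(X, columns):
    df = pd.DataFrame(X, columns=columns)
    df.insert(0, "sample_id", [f"s{i}" for i in range(len(df))])
    return df


def test_meta_lung_function_equals_pc1_on_complete_table():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 4)) @ rng.normal(size=(4, 4))
    cols = ["DLCO_SB_percent", "FVC", "FEV1", "TLC"]
    mlf = fs.meta_lung_function(_clinical_from(X, cols), cols)
    Z = (X - X.mean(0)) / X.std(0)
    U, D, Vt = np.linalg.svd(Z, full_matrices=False)
    pc1 = Z @ Vt[0]
    r = np.corrcoef(mlf.scores, pc1)[0, 1]
    assert abs(r) == pytest.approx(1.0, abs=1e-10)
    assert mlf.loadings["DLCO_SB_percent"] > 0


def test_meta_lung_function_exact_rank1_recovery():
    rng = np.random.default_rng(4)
    u = rng.normal(size=20)
    v = rng.uniform(1, 2, size=5)
    X = np.outer(u, v)
    X_missing = X.copy()
    X_missing[3, 2] = np.nan
    cols = [f"lf{i}" for i in range(5)]
    mlf = fs.meta_lung_function(
        _clinical_from(X_missing, cols), cols, anchor_column="lf0", tol=1e-10
    )
    assert mlf.converged
    # the EM completion reproduces the masked entry of the rank-1 matrix
    work = _clinical_from(X_missing, cols).set_index("sample_id")[cols]
    # recompute completion through the public scores: project back
    # instead, verify via score correlation with the latent factor u
    assert abs(np.corrcoef(mlf.scores, u)[0, 1]) > 1 - 1e-8


def test_meta_lung_function_rejects_majority_missing_column():
    X = np.random.default_rng(5).normal(size=(10, 3))
    X[:6, 0] = np.nan
    cols = ["a", "b", "c"]
    with pytest.raises(fs.ValidationError, match="missingness"):
        fs.meta_lung_function(_clinical_from(X, cols), cols)


def test_impute_identity_on_complete_table():
    table = _table(np.random.default_rng(6).normal(20, 1, (8, 10)))
    out = fs.impute_proteins(table)
    pd.testing.assert_frame_equal(out.intensities, table.intensities)


def test_impute_beats_mean_imputation_and_is_deterministic():
    rng = np.random.default_rng(7)
    latent = rng.normal(size=(40,))
    truth = 20 + np.outer(rng.normal(1, 0.3, 30), latent) + rng.normal(0, 0.3, (30, 40))
    mask = rng.random(truth.shape) < 0.15
    observed = np.where(mask, np.nan, truth)
    table = _table(observed)
    imp1 = fs.impute_proteins(table, estimator="forest", seed=1)
    imp2 = fs.impute_proteins(table, estimator="forest", seed=1)
    pd.testing.assert_frame_equal(imp1.intensities, imp2.intensities)
    rmse_model = np.sqrt(np.nanmean((imp1.intensities.to_numpy() - truth)[mask] ** 2))
    col_means = np.nanmean(observed, axis=1, keepdims=True)
    rmse_mean = np.sqrt(np.nanmean((np.broadcast_to(col_means, truth.shape) - truth)[mask] ** 2))
    assert rmse_model < rmse_mean
    assert imp1.imputed_mask.to_numpy().sum() == mask.sum()


def test_lungfunction_regression_exact_predictor_and_oracle():
    rng = np.random.default_rng(8)
    n = 30
    meta = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
    age = pd.Series(rng.uniform(40, 75, n), index=meta.index)
    gender = pd.Series(["F", "M"] * (n // 2), index=meta.index)
    X = rng.normal(size=(5, n))
    X[0] = meta.to_numpy()  # protein identical to the outcome
    table = _table(X, samples=list(meta.index))
    out = fs.lungfunction_regression(table, meta, age, gender)
    hit = out[out["protein"] == "P0"].iloc[0]
    assert hit["coefficient"] > 0
    assert hit["p_value"] < 1e-12
    # oracle comparison on an ordinary protein
    import statsmodels.api as sm

    x1 = X[1]
    design = sm.add_constant(
        np.column_stack([x1, age.to_numpy(), (gender == "M").to_numpy(float)])
    )
    fit = sm.OLS(meta.to_numpy(), design).fit()
    row = out[out["protein"] == "P1"].iloc[0]
    assert row["t_value"] == pytest.approx(fit.tvalues[1], abs=1e-8)
    assert row["coefficient"] == pytest.approx(fit.params[1], abs=1e-10)


def test_lungfunction_regression_null_calibration():
    rng = np.random.default_rng(9)
    n = 40
    meta = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
    age = pd.Series(rng.uniform(40, 75, n), index=meta.index)
    gender = pd.Series(["F", "M"] * (n // 2), index=meta.index)
    table = _table(rng.normal(size=(400, n)), samples=list(meta.index))
    out = fs.lungfunction_regression(table, meta, age, gender)
    frac = (out["p_value"] < 0.05).mean()
    assert 0.02 < frac < 0.08


def test_elf_score_zero_for_identical_compartments_and_antisymmetric():
    rng = np.random.default_rng(10)
    shared = rng.uniform(10, 100, size=(20, 6))
    balf = _table(shared, scale="raw")
    tissue = _table(shared * 3.0, scale="raw")  # per-sample loading cancels out
    out = fs.elf_score(balf, tissue)
    # identical relative abundances → raw score 0 everywhere
    np.testing.assert_allclose(out["raw_score"], 0.0, atol=1e-12)
    # antisymmetry on distinct compartments
    tissue2 = _table(rng.uniform(10, 100, size=(20, 6)), scale="raw")
    fwd = fs.elf_score(balf, tissue2)
    rev = fs.elf_score(tissue2, balf)
    np.testing.assert_allclose(fwd["raw_score"], -rev["raw_score"], atol=1e-12)


def test_elf_score_ranks_planted_secreted_proteins_high():
    rng = np.random.default_rng(11)
    tissue_vals = rng.uniform(50, 60, size=(30, 8))
    balf_vals = tissue_vals.copy()
    balf_vals[:3] *= 8.0  # secreted analogs enriched in the fluid
    balf = _table(balf_vals, scale="raw")
    tissue = _table(tissue_vals, scale="raw")
    out = fs.elf_score(balf, tissue)
    top = out["elf_zscore"].nlargest(3).index
    assert set(top) == {"P0", "P1", "P2"}


def test_top_abundant_mass_fraction_behaviour():
    rng = np.random.default_rng(12)
    ref = _table(np.vstack([np.full((2, 4), 1000.0), rng.uniform(1, 5, (18, 4))]), scale="raw")
    tab = _table(rng.uniform(1, 10, (20, 6)), scale="raw")
    frac = top_abundant_mass_fraction(tab, ref, n_top=2)
    rel = relative_abundance(tab)
    np.testing.assert_allclose(frac, rel.loc[["P0", "P1"]].sum(axis=0))
    assert ((frac >= 0) & (frac <= 1)).all()
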
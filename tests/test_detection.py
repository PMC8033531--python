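import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import fibroscope as fs
from fibroscope import CountMatrix, DetectionProfile
from fibroscope.detection import ols_outcome_test


def closed_form_ols(X, y, j):
    """Independent textbook OLS oracle: beta = (XᵀX)⁻¹Xᵀy, residual-based SE."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    s2 = resid @ resid / (len(y) - X.shape[1])
    se = np.sqrt(s2 * XtX_inv[j, j])
    return beta[j], beta[j] / se


def _profile_matrix():
    counts = np.array([[0, 0], [1, 0], [2, 0], [0, 0]])
    meta = pd.DataFrame(
        {
            "sample_id": ["s1"] * 4,
            "cohort_id": ["c"] * 4,
            "disease_status": ["ILD"] * 4,
            "cell_type": ["A"] * 4,
        }
    )
    return CountMatrix(
        sp.csr_matrix(counts),
        np.array([f"c{i}" for i in range(4)], dtype=object),
        np.array(["g1", "gzero"], dtype=object),
        meta,
    ).validate()


@pytest.mark.parametrize("threshold, expected", [(0, 0.5), (1, 0.25)])
def test_detection_fraction_direct_count(threshold, expected):
    prof = fs.detection_profile(_profile_matrix(), detect_threshold=threshold)
    assert prof.values[0, 0] == expected
    # all-zero gene is 0 in every row
    assert prof.values[0, 1] == 0.0


def test_detection_profile_rejects_unlabeled_cells():
    cm = _profile_matrix()
    cm.cell_meta.loc[0, "cell_type"] = None
    with pytest.raises(fs.ValidationError):
        fs.detection_profile(cm)


def test_detection_profile_min_cells_drops_small_groups():
    cm = _profile_matrix()
    cm.cell_meta.loc[0, "cell_type"] = "rare"
    prof = fs.detection_profile(cm, min_cells=2)
    assert "rare" not in set(prof.rows["cell_type"])


def test_ols_matches_independent_closed_form():
    rng = np.random.default_rng(42)
    X = np.column_stack([np.ones(8), rng.integers(0, 2, 8), rng.normal(size=(8, 3))])
    Y = rng.normal(size=(8, 6))
    coef, t, p = ols_outcome_test(X, Y, 1)
    for g in range(Y.shape[1]):
        b_ref, t_ref = closed_form_ols(X, Y[:, g], 1)
        assert coef[g] == pytest.approx(b_ref, abs=1e-10)
        assert t[g] == pytest.approx(t_ref, abs=1e-8)


def test_t_and_coefficient_share_sign():
    rng = np.random.default_rng(1)
    X = np.column_stack([np.ones(12), rng.normal(size=(12, 2))])
    Y = rng.normal(size=(12, 20))
    coef, t, p = ols_outcome_test(X, Y, 1)
    assert (np.sign(coef) == np.sign(t)).all()
    assert ((p >= 0) & (p <= 1)).all()


def test_ols_t_invariant_to_affine_covariate_rescaling():
    rng = np.random.default_rng(7)
    X = np.column_stack([np.ones(15), rng.integers(0, 2, 15), rng.normal(size=(15, 2))])
    Y = rng.normal(size=(15, 5))
    _, t1, _ = ols_outcome_test(X, Y, 1)
    X2 = X.copy()
    X2[:, 2] = 100.0 * X2[:, 2] - 7.0
    X2[:, 3] = -0.01 * X2[:, 3] + 3.0
    _, t2, _ = ols_outcome_test(X2, Y, 1)
    np.testing.assert_allclose(t1, t2, atol=1e-9)


def _toy_profile(values, samples, cell_type="A"):
    rows = pd.DataFrame(
        {"sample_id": samples, "cell_type": cell_type, "n_cells": 10}
    )
    return DetectionProfile(
        values=np.asarray(values, dtype=float),
        rows=rows,
        gene_ids=np.array([f"g{i}" for i in range(np.asarray(values).shape[1])], dtype=object),
    ).validate()


def _toy_samples(n, n_cohorts=1):
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "cohort_id": [f"c{i % n_cohorts}" for i in range(n)],
            "disease_status": ["control", "ILD"] * (n // 2),
            "age": rng.uniform(40, 75, n).round(),
            "gender": ["F", "F", "M", "M"] * (n // 4),
            "n_cells": rng.integers(50, 200, n),
            "total_umi": rng.integers(10_000, 50_000, n),
        }
    )


def test_constant_gene_gets_zero_coefficient_and_p_one():
    samples = _toy_samples(12)
    values = np.column_stack(
        [np.full(12, 0.25), np.random.default_rng(2).uniform(0.1, 0.9, 12)]
    )
    prof = _toy_profile(values, samples["sample_id"])
    de, _ = fs.fit_detection_regression(prof, samples)
    const = de[de["gene"] == "g0"].iloc[0]
    assert const["coefficient"] == 0.0
    assert const["p_value"] == 1.0


def test_collinear_outcome_cohort_skipped_with_reason():
    samples = _toy_samples(12)
    # cohort perfectly aligned with disease: collinear design
    samples["cohort_id"] = np.where(samples["disease_status"] == "ILD", "cA", "cB")
    prof = _toy_profile(np.random.default_rng(3).uniform(0, 1, (12, 4)), samples["sample_id"])
    with pytest.raises(fs.ValidationError, match="rank-deficient"):
        fs.fit_detection_regression(prof, samples)


def test_too_few_samples_per_level_skipped():
    samples = _toy_samples(12)
    samples["disease_status"] = ["ILD"] * 10 + ["control"] * 2
    prof = _toy_profile(np.random.default_rng(4).uniform(0, 1, (12, 3)), samples["sample_id"])
    with pytest.raises(fs.ValidationError, match="smaller outcome level"):
        fs.fit_detection_regression(prof, samples)


def test_bh_adjustment_closed_form_and_properties():
    de = pd.DataFrame(
        {"cell_type": "A", "gene": ["g1", "g2", "g3"], "p_value": [0.01, 0.02, 0.03]}
    )
    out = fs.adjust_pvalues(de)
    np.testing.assert_allclose(out["adjusted_p"], [0.03, 0.03, 0.03])
    single = fs.adjust_pvalues(
        pd.DataFrame({"cell_type": "A", "gene": ["g"], "p_value": [0.2]})
    )
    assert single["adjusted_p"].iloc[0] == pytest.approx(0.2)


def test_bh_matches_independent_step_up_on_random_vectors():
    def step_up_bh(p):
        """Independent BH oracle: sorted step-up with cumulative minimum."""
        p = np.asarray(p)
        n = len(p)
        order = np.argsort(p)
        ranked = p[order] * n / np.arange(1, n + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(n)
        out[order] = np.minimum(ranked, 1.0)
        return out

    rng = np.random.default_rng(5)
    for _ in range(5):
        p = rng.uniform(size=50)
        de = pd.DataFrame({"cell_type": "A", "gene": np.arange(50), "p_value": p})
        out = fs.adjust_pvalues(de)
        np.testing.assert_allclose(out["adjusted_p"], step_up_bh(p), atol=1e-12)
        assert (out["adjusted_p"] >= out["p_value"] - 1e-15).all()
        assert (out["adjusted_p"] <= 1.0).all()


def test_bh_is_idempotent():
    rng = np.random.default_rng(6)
    de = pd.DataFrame({"cell_type": "A", "gene": np.arange(30), "p_value": rng.uniform(size=30)})
    once = fs.adjust_pvalues(de)
    again = fs.adjust_pvalues(once.assign(p_value=once["adjusted_p"]))
    assert (again["adjusted_p"] >= once["adjusted_p"] - 1e-12).all()


def test_unknown_adjustment_method_rejected():
    de = pd.DataFrame({"cell_type": "A", "gene": ["g"], "p_value": [0.5]})
    with pytest.raises(fs.ValidationError):
        fs.adjust_pvalues(de, method="bonferroni?")


def test_sqrt_transform_preserves_detection_ordering():
    vals = np.sort(np.random.default_rng(8).uniform(0, 1, 50))
    assert (np.diff(np.sqrt(vals)) >= 0).all()


def test_concordance_self_is_one_and_null_centered_at_zero():
    rng = np.random.default_rng(9)
    t1 = pd.DataFrame(
        {"cell_type": "A", "gene": [f"g{i}" for i in range(500)], "t_value": rng.normal(size=500)}
    )
    t2 = t1.assign(t_value=rng.normal(size=500))
    mat = fs.crosscohort_concordance({"a": t1, "b": t2})
    assert mat.loc["a", "a"] == 1.0
    assert abs(mat.loc["a", "b"]) < 0.15
    assert mat.loc["a", "b"] == mat.loc["b", "a"]


def test_concordance_flags_insufficient_overlap():
    t1 = pd.DataFrame({"cell_type": "A", "gene": ["g1", "g2"], "t_value": [1.0, 2.0]})
    t2 = pd.DataFrame({"cell_type": "A", "gene": ["g9", "g8"], "t_value": [1.0, 2.0]})
    mat = fs.crosscohort_concordance({"a": t1, "b": t2})
    assert np.isnan(mat.loc["a", "b"])


def test_shared_planted_effects_give_positive_cross_cohort_concordance():
    from conftest import small_config

    cfg = small_config(
        samples_per_cohort_per_arm=4,
        cells_per_sample=(150, 200),
        detection_shift=0.3,
    )
    cm, samples, truth = fs.simulate_cohorts(cfg, seed=19)
    prof = fs.detection_profile(cm)
    results = {}
    for cohort in samples["cohort_id"].unique():
        sub_samples = samples[samples["cohort_id"] == cohort]
        mask = prof.rows["sample_id"].isin(sub_samples["sample_id"]).to_numpy()
        sub_prof = DetectionProfile(
            values=prof.values[mask],
            rows=prof.rows.loc[mask].reset_index(drop=True),
            gene_ids=prof.gene_ids,
            threshold=prof.threshold,
        )
        de, _ = fs.fit_detection_regression(sub_prof, sub_samples)
        results[cohort] = de[de["cell_type"] == "AT2"]
    mat = fs.crosscohort_concordance(results)
    off_diag = mat.to_numpy()[~np.eye(len(mat), dtype=bool)]
    assert (off_diag > 0.1).all()
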
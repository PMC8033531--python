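import numpy as np
import pandas as pd
import pytest

import fibroscope as fs
from fibroscope import ProteinTable
from conftest import small_config


def test_celltype_frequencies_hand_example():
    meta = pd.DataFrame(
        {"sample_id": ["s1"] * 4 + ["s2"] * 2, "cell_type": ["A", "A", "B", "C", "A", "A"]}
    )
    props = fs.celltype_frequencies(meta)
    assert props.loc["s1"].tolist() == [0.5, 0.25, 0.25]
    assert props.loc["s2", "A"] == 1.0
    assert props.loc["s2", "B"] == 0.0  # global vocabulary, absent type = 0
    np.testing.assert_allclose(props.sum(axis=1), 1.0)


def test_proportion_pca_reconstruction_and_determinism():
    rng = np.random.default_rng(0)
    props = pd.DataFrame(
        rng.dirichlet(np.ones(4) * 5, size=12),
        index=[f"s{i}" for i in range(12)],
        columns=list("ABCD"),
    )
    scores, loadings, evr = fs.proportion_pca(props)
    centered = props.to_numpy() - props.to_numpy().mean(axis=0)
    np.testing.assert_allclose(scores.to_numpy() @ loadings.to_numpy().T, centered, atol=1e-10)
    scores2, _, _ = fs.proportion_pca(props)
    pd.testing.assert_frame_equal(scores, scores2)
    assert evr.sum() == pytest.approx(1.0)


def test_proportion_pca_separates_planted_groups():
    cfg = small_config()
    props, labels, _ = fs.simulate_proportions(cfg, seed=1, n_per_arm=25)
    scores, _, _ = fs.proportion_pca(props)
    gaps = [
        abs(scores.loc[labels == "ILD", pc].mean() - scores.loc[labels == "control", pc].mean())
        / scores[pc].std()
        for pc in ("PC1", "PC2")
    ]
    assert max(gaps) > 1.0


def test_proportion_pca_too_few_samples():
    props = pd.DataFrame(np.eye(2), columns=["A", "B"])
    with pytest.raises(fs.ValidationError):
        fs.proportion_pca(props)


def test_classifier_deterministic_and_errors():
    cfg = small_config()
    props, labels, _ = fs.simulate_proportions(cfg, seed=2, n_per_arm=15)
    res1 = fs.disease_classifier_cv(props, labels, n_trees=50, seed=3)
    res2 = fs.disease_classifier_cv(props, labels, n_trees=50, seed=3)
    np.testing.assert_array_equal(res1["fold_accuracies"], res2["fold_accuracies"])
    with pytest.raises(fs.ValidationError, match="classes"):
        fs.disease_classifier_cv(props, pd.Series("ILD", index=props.index), n_trees=10)
    with pytest.raises(fs.ValidationError, match="exceeds"):
        fs.disease_classifier_cv(props, labels, k=20, n_trees=10)


def test_quantile_normalization_makes_sorted_columns_identical():
    rng = np.random.default_rng(4)
    table = pd.DataFrame(rng.normal(size=(50, 6)) * rng.uniform(1, 5, 6))
    qn, ref = fs.quantile_normalize(table)
    sorted_cols = np.sort(qn.to_numpy(), axis=0)
    for j in range(1, 6):
        np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0], atol=1e-12)
    np.testing.assert_allclose(sorted_cols[:, 0], ref, atol=1e-12)


def test_quantile_normalization_tie_handling():
    # ties within a column share the average of the reference values they span
    table = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 3.0, 4.0]})
    qn, ref = fs.quantile_normalize(table)
    np.testing.assert_allclose(ref, [1.5, 2.0, 4.5])
    assert qn.loc[0, "a"] == qn.loc[1, "a"] == pytest.approx((1.5 + 2.0) / 2)
    # permuting tied rows leaves the result unchanged
    perm = table.iloc[[1, 0, 2]].reset_index(drop=True)
    qn_perm, _ = fs.quantile_normalize(perm)
    np.testing.assert_allclose(qn_perm.to_numpy(), qn.iloc[[1, 0, 2]].to_numpy())


def test_quantile_normalize_scale_feature_moments():
    rng = np.random.default_rng(5)
    table = pd.DataFrame(rng.normal(size=(30, 8)))
    scaled, params = fs.quantile_normalize_scale(table)
    np.testing.assert_allclose(scaled.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(scaled.std(axis=1, ddof=0), 1.0, atol=1e-12)


def test_insilico_bulk_hand_example_and_conservation(simulated_cohort):
    import scipy.sparse as sp
    from fibroscope import CountMatrix

    counts = np.array([[0, 2], [4, 2]])
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s1"],
            "cohort_id": ["c"] * 2,
            "disease_status": ["ILD"] * 2,
            "cell_type": ["x", "y"],
        }
    )
    cm = CountMatrix(
        sp.csr_matrix(counts),
        np.array(["c1", "c2"], dtype=object),
        np.array(["g1", "g2"], dtype=object),
        meta,
    ).validate()
    bulk = fs.insilico_bulk(cm)
    assert bulk.loc["g1", "s1"] == 2.0
    assert bulk.loc["g2", "s1"] == 2.0

    cm_big, samples, _ = simulated_cohort
    bulk_big = fs.insilico_bulk(cm_big)
    # conservation: mean × n_cells = per-sample gene totals
    st = samples.set_index("sample_id")
    for s in list(bulk_big.columns)[:3]:
        idx = (cm_big.cell_meta["sample_id"] == s).to_numpy()
        totals = np.asarray(cm_big.counts[np.flatnonzero(idx)].sum(axis=0)).ravel()
        np.testing.assert_allclose(bulk_big[s] * st.loc[s, "n_cells"], totals, atol=1e-8)


def test_insilico_bulk_matches_brute_force(simulated_cohort):
    cm, _, _ = simulated_cohort
    bulk = fs.insilico_bulk(cm)
    rng = np.random.default_rng(6)
    dense = np.asarray(cm.counts.todense())
    for s in rng.choice(bulk.columns, 3, replace=False):
        mask = (cm.cell_meta["sample_id"] == s).to_numpy()
        np.testing.assert_allclose(bulk[s], dense[mask].mean(axis=0), atol=1e-12)


def _training_setup(seed=0, n=60, n_prot=40, r_strength=0.8):
    rng = np.random.default_rng(seed)
    dlco = pd.Series(rng.normal(60, 15, n), index=[f"s{i}" for i in range(n)], name="DLCO")
    X = rng.normal(20, 1, (n_prot, n))
    # first 10 proteins linked to DLCO
    X[:10] += r_strength * ((dlco.to_numpy() - dlco.mean()) / dlco.std())[None, :]
    proteins = [f"G{i:04d}" for i in range(n_prot)]
    table = ProteinTable(
        intensities=pd.DataFrame(X, index=proteins, columns=dlco.index), scale_tag="log2"
    )
    return table, dlco, proteins


def test_train_rejects_unreachable_threshold_and_empty_vocab():
    table, dlco, proteins = _training_setup()
    with pytest.raises(fs.ValidationError, match="no features"):
        fs.train_lungfunction_model(table, dlco, proteins, r_threshold=1.0)
    with pytest.raises(fs.ValidationError, match="no features"):
        fs.train_lungfunction_model(table, dlco, ["UNRELATED"], r_threshold=0.2)


def test_planted_features_selected_and_model_beats_mean():
    table, dlco, proteins = _training_setup(seed=1)
    model = fs.train_lungfunction_model(table, dlco, proteins, n_trees=100, seed=2)
    assert set(f"G{i:04d}" for i in range(10)) <= set(model.feature_ids)
    pred = model.regressor.predict(
        fs.quantile_normalize_scale(table.intensities)[0].loc[model.feature_ids].T.to_numpy()
    )
    ss_res = ((pred - dlco.to_numpy()) ** 2).sum()
    ss_tot = ((dlco - dlco.mean()) ** 2).sum()
    assert 1 - ss_res / ss_tot > 0


def test_predict_from_bulk_errors_on_missing_features():
    table, dlco, proteins = _training_setup(seed=3)
    model = fs.train_lungfunction_model(table, dlco, proteins, n_trees=50, seed=4)
    bulk = pd.DataFrame(
        np.random.default_rng(5).uniform(size=(3, 4)), index=["X1", "X2", "X3"]
    )
    with pytest.raises(fs.ValidationError, match="lacks model features"):
        fs.predict_from_bulk(model, bulk)


def test_transfer_self_consistency_through_identity_bulk():
    table, dlco, proteins = _training_setup(seed=6)
    model = fs.train_lungfunction_model(table, dlco, proteins, n_trees=100, seed=7)
    # bulk built by pushing the training proteins through an identity mapping
    bulk = table.intensities.copy()
    pred = fs.predict_from_bulk(model, bulk)
    train_scaled = fs.quantile_normalize_scale(table.intensities)[0]
    fit = model.regressor.predict(train_scaled.loc[model.feature_ids].T.to_numpy())
    assert np.corrcoef(pred.to_numpy(), fit)[0, 1] > 0.9


def test_transfer_direction_on_linked_synthetic_data():
    cfg = small_config(n_proteins=150, clinical_missing_rate=0.0)
    cm, samples, truth = fs.simulate_cohorts(cfg, seed=8)
    pt, clin, truth2 = fs.simulate_balf_proteome(truth, cfg, seed=9)
    imp = fs.impute_proteins(pt, estimator="ridge")
    dlco = clin.set_index("sample_id")["DLCO_SB_percent"].rename("DLCO")
    model = fs.train_lungfunction_model(
        imp, dlco, [str(g) for g in cm.gene_ids], n_trees=100, seed=10
    )
    pred = fs.predict_from_bulk(model, fs.insilico_bulk(cm))
    status = samples.set_index("sample_id")["disease_status"]
    assert pred[status == "ILD"].mean() < pred[status == "control"].mean()
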
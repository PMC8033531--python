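"""Machine-learning stages: proportion-based disease classification and
cross-modal protein → transcriptome lung-function prediction.

The first stage asks whether cell-type composition alone separates disease
from control: a random forest is cross-validated on per-sample cell-type
proportions, with a permutation null (same procedure on shuffled labels) and
fold-averaged feature importances.

The second stage trains a random forest to predict lung function (DLCO) from
quantile-normalized, scaled body-fluid protein intensities — keeping only
features correlated with lung function (|r| > 0.2) and present in the
single-cell gene vocabulary — and then transfers the model to an "in-silico
bulk" transcriptome (per-sample mean expression count over all cells), which
is quantile normalized and scaled within its own modality before prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import StratifiedKFold

from .datatypes import CountMatrix, ProteinTable, ValidationError


def celltype_frequencies(cell_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample cell-type proportions over the global type vocabulary.

    Rows sum to 1; cell types absent from a sample get 0.
    """
    if cell_meta["cell_type"].isna().any():
        raise ValidationError("cells without cell_type label")
    counts = pd.crosstab(cell_meta["sample_id"], cell_meta["cell_type"])
    props = counts.div(counts.sum(axis=1), axis=0)
    return props


def proportion_pca(
    proportions: pd.DataFrame, n_components: int | None = None, scale: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Centered PCA of the proportion table with a deterministic sign.

    Each component is oriented so its largest-|loading| entry is positive.
    Returns (scores samples × PCs, loadings types × PCs, explained-variance
    ratios).
    """
    if len(proportions) < 3:
        raise ValidationError("PCA needs at least 3 samples")
    X = proportions.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = X / np.where(sd > 0, sd, 1.0)
    U, D, Vt = np.linalg.svd(X, full_matrices=False)
    k = n_components or min(X.shape)
    k = min(k, min(X.shape))
    flip = np.sign(Vt[np.arange(k), np.abs(Vt[:k]).argmax(axis=1)])
    flip = np.where(flip == 0, 1.0, flip)
    scores = (U[:, :k] * D[:k]) * flip
    loadings = Vt[:k].T * flip
    evr = D[:k] ** 2 / (D**2).sum()
    pcs = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores, index=proportions.index, columns=pcs),
        pd.DataFrame(loadings, index=proportions.columns, columns=pcs),
        evr,
    )


def disease_classifier_cv(
    proportions: pd.DataFrame,
    labels: pd.Series,
    k: int = 5,
    n_trees: int = 500,
    n_permutations: int = 0,
    seed: int = 17,
) -> dict:
    """Stratified k-fold random-forest classification of disease status.

    Returns fold accuracies, their mean, fold-averaged feature importances,
    and (optionally) the permutation-null distribution of mean CV accuracy
    obtained by rerunning the whole procedure on label-shuffled data.
    """
    y = labels.reindex(proportions.index)
    classes = y.unique()
    if len(classes) < 2:
        raise ValidationError("both classes must be present")
    X = proportions.to_numpy(dtype=float)
    yv = y.to_numpy()

    def _cv(yvec: np.ndarray, rs: int) -> tuple[np.ndarray, np.ndarray]:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        accs, imps = [], []
        for train, test in skf.split(X, yvec):
            clf = RandomForestClassifier(
                n_estimators=n_trees, random_state=rs, n_jobs=1
            )
            clf.fit(X[train], yvec[train])
            accs.append(float((clf.predict(X[test]) == yvec[test]).mean()))
            imps.append(clf.feature_importances_)
        return np.array(accs), np.mean(imps, axis=0)

    min_class = int(pd.Series(yv).value_counts().min())
    if k > min_class:
        raise ValidationError(f"k={k} exceeds the smaller class count {min_class}")
    fold_acc, importances = _cv(yv, seed)
    rng = np.random.default_rng(seed)
    null_acc = []
    for _ in range(n_permutations):
        shuffled = rng.permutation(yv)
        accs, _ = _cv(shuffled, int(rng.integers(0, 2**31 - 1)))
        null_acc.append(float(accs.mean()))
    return {
        "fold_accuracies": fold_acc,
        "mean_accuracy": float(fold_acc.mean()),
        "importances": pd.Series(
            importances, index=proportions.columns, name="importance"
        ).sort_values(ascending=False),
        "permuted_accuracies": np.array(null_acc),
        "majority_class_rate": float(pd.Series(yv).value_counts(normalize=True).max()),
    }


def quantile_normalize(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Force every column (sample) onto the common quantile reference.

    The reference is the mean of the column-sorted value vectors; ties within
    a column receive the average of the reference values they span.  Returns
    (normalized table, reference distribution).  After this step all columns
    have identical sorted values (up to tie-averaging).
    """
    X = table.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("quantile normalization requires complete data")
    n = X.shape[0]
    ref = np.sort(X, axis=0).mean(axis=1)
    if X.shape[1] == 1:
        return table.copy(), ref  # single sample: identity
    from scipy.stats import rankdata

    out = np.empty_like(X)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, ref)
    return pd.DataFrame(out, index=table.index, columns=table.columns), ref


def quantile_normalize_scale(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Quantile-normalize columns, then z-score each feature across samples.

    Returns the transformed features × samples table and the stored
    parameters (quantile reference, per-feature mean/sd) for reuse.
    """
    qn, ref = quantile_normalize(table)
    mean = qn.mean(axis=1)
    sd = qn.std(axis=1, ddof=0)
    sd_safe = sd.where(sd > 0, 1.0)
    scaled = qn.sub(mean, axis=0).div(sd_safe, axis=0)
    params = {"quantile_reference": ref, "feature_mean": mean, "feature_sd": sd}
    return scaled, params


@dataclass
class TransferModel:
    """Protein-trained lung-function regressor transferable to bulk expression."""

    feature_ids: list[str]
    regressor: RandomForestRegressor
    target_name: str = "DLCO"
    training_params: dict = field(default_factory=dict)


def train_lungfunction_model(
    protein_table: ProteinTable,
    lung_function: pd.Series,
    scrna_gene_vocab: list[str],
    r_threshold: float = 0.2,
    n_trees: int = 500,
    seed: int = 17,
) -> TransferModel:
    """Train the cross-modal lung-function regressor on protein data.

    Proteins are quantile normalized and scaled; only features with
    |Pearson r| > ``r_threshold`` against lung function *and* an id present
    in the single-cell gene vocabulary (case-insensitive symbol match) are
    used to fit the random forest.
    """
    if protein_table.intensities.isna().to_numpy().any():
        raise ValidationError("protein table must be imputed before training")
    scaled, params = quantile_normalize_scale(protein_table.intensities)
    y = lung_function.reindex(scaled.columns).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValidationError("lung function must be available for all training samples")
    vocab = {str(g).upper() for g in scrna_gene_vocab}
    feats = []
    yc = y - y.mean()
    ysd = y.std(ddof=0)
    for protein in scaled.index:
        if str(protein).upper() not in vocab:
            continue
        x = scaled.loc[protein].to_numpy(dtype=float)
        xsd = x.std(ddof=0)
        if xsd == 0 or ysd == 0:
            continue
        r = float(np.mean((x - x.mean()) * yc) / (xsd * ysd))
        if abs(r) > r_threshold:
            feats.append(str(protein))
    if not feats:
        raise ValidationError(
            f"no features passed |r| > {r_threshold} with a vocabulary overlap of "
            f"{sum(1 for p in scaled.index if str(p).upper() in vocab)} proteins"
        )
    reg = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    reg.fit(scaled.loc[feats].T.to_numpy(), y)
    return TransferModel(
        feature_ids=feats,
        regressor=reg,
        target_name=lung_function.name or "DLCO",
        training_params={
            "r_threshold": r_threshold,
            "n_trees": n_trees,
            "seed": seed,
            "quantile_reference": params["quantile_reference"],
            "feature_mean": params["feature_mean"].loc[feats],
            "feature_sd": params["feature_sd"].loc[feats],
        },
    )


def insilico_bulk(matrix: CountMatrix) -> pd.DataFrame:
    """Genes × samples mean raw count over all cells of each sample."""
    meta = matrix.cell_meta
    samples = sorted(meta["sample_id"].unique())
    cols = {}
    for s in samples:
        idx = np.flatnonzero((meta["sample_id"] == s).to_numpy())
        cols[s] = np.asarray(matrix.counts[idx].mean(axis=0)).ravel()
    return pd.DataFrame(cols, index=[str(g) for g in matrix.gene_ids])


def predict_from_bulk(model: TransferModel, bulk: pd.DataFrame) -> pd.Series:
    """Predict lung function from a bulk expression table.

    The bulk table (genes × samples) is quantile normalized and scaled
    within its own modality, restricted to the model's features
    (case-insensitive id match; missing features are an error), and fed to
    the trained regressor.
    """
    upper_index = pd.Index([str(g).upper() for g in bulk.index])
    lookup = pd.Series(np.arange(len(bulk)), index=upper_index)
    missing = [f for f in model.feature_ids if f.upper() not in upper_index]
    if missing:
        raise ValidationError(f"bulk table lacks model features: {missing}")
    rows = [int(lookup[f.upper()]) for f in model.feature_ids]
    sub = bulk.iloc[rows]
    scaled, _ = quantile_normalize_scale(sub)
    X = scaled.to_numpy().T
    pred = model.regressor.predict(X)
    return pd.Series(pred, index=bulk.columns, name=f"predicted_{model.target_name}")
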
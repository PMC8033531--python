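"""Meta-cell gene–gene correlation and pseudotime bin/smooth curves.

Single-cell UMI counts are too sparse for reliable pairwise gene
correlations, so cells are first aggregated into small clusters of
transcriptionally similar cells ("meta-cells") and Pearson correlations are
computed across the cluster averages, which damps dropout noise and raises
true correlations.  A cross-cohort consensus keeps only anchor-gene
correlates with a common direction in every cohort.  Trajectory curves
average expression within equal-count pseudotime bins and smooth the bin
means with a short moving average; pseudotime itself comes from outside
(any diffusion-pseudotime routine, or a planted latent in simulations)
through a plain per-cell array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ValidationError


@dataclass
class MetaCellMatrix:
    """Cluster × gene mean expression (log-normalized scale) + cluster sizes."""

    means: pd.DataFrame  # clusters × genes
    sizes: pd.Series  # per-cluster cell counts
    source: str = ""


@dataclass
class TrajectoryCurves:
    """Equal-count pseudotime bins with per-gene binned and smoothed means."""

    bin_centers: np.ndarray
    bin_sizes: np.ndarray
    means: pd.DataFrame  # genes × bins
    smoothed: pd.DataFrame  # genes × bins
    window: int


def leiden_cluster_cells(
    expr: np.ndarray,
    target_n_clusters: int = 50,
    random_state: int = 0,
    n_pcs: int = 30,
    n_neighbors: int = 15,
    max_bisections: int = 12,
) -> np.ndarray:
    """Default clustering backend: PCA → kNN graph → Leiden communities.

    The Leiden resolution is bisected until the cluster count lands within
    [0.8, 1.2] × ``target_n_clusters`` (or bisection exhausts, returning the
    closest labeling seen).
    """
    import scanpy as sc
    from anndata import AnnData

    ad = AnnData(np.asarray(expr, dtype=np.float32))
    n_pcs = min(n_pcs, min(ad.shape) - 1)
    sc.pp.pca(ad, n_comps=n_pcs, random_state=random_state)
    sc.pp.neighbors(ad, n_neighbors=min(n_neighbors, ad.n_obs - 1), random_state=random_state)

    lo, hi = 0.05, 50.0
    best = None
    for _ in range(max_bisections):
        res = np.sqrt(lo * hi)
        sc.tl.leiden(
            ad,
            resolution=float(res),
            key_added="leiden",
            random_state=random_state,
            flavor="igraph",
            n_iterations=2,
            directed=False,
        )
        labels = ad.obs["leiden"].astype(int).to_numpy()
        n = labels.max() + 1
        if best is None or abs(n - target_n_clusters) < abs(best[1] - target_n_clusters):
            best = (labels, n)
        if 0.8 * target_n_clusters <= n <= 1.2 * target_n_clusters:
            return labels
        if n < target_n_clusters:
            lo = res
        else:
            hi = res
    return best[0]


def metacell_average(
    expr,
    labels: np.ndarray | None = None,
    target_n_clusters: int = 50,
    min_size: int = 5,
    cluster_fn=None,
    random_state: int = 0,
) -> MetaCellMatrix:
    """Average log-normalized expression over small cell clusters.

    ``expr`` is cells × genes (DataFrame or array).  Clustering labels can be
    supplied directly, produced by a custom ``cluster_fn(expr_array)``, or by
    the default PCA/kNN/Leiden backend targeting ``target_n_clusters``
    clusters.  Clusters smaller than ``min_size`` are merged into the nearest
    cluster by centroid Euclidean distance.
    """
    df = pd.DataFrame(expr) if not isinstance(expr, pd.DataFrame) else expr
    X = df.to_numpy(dtype=float)
    if labels is None:
        if X.shape[0] < target_n_clusters:
            raise ValidationError(
                f"{X.shape[0]} cells cannot form {target_n_clusters} clusters"
            )
        if cluster_fn is not None:
            labels = np.asarray(cluster_fn(X))
        else:
            labels = leiden_cluster_cells(
                X, target_n_clusters=target_n_clusters, random_state=random_state
            )
    labels = np.asarray(labels)
    if len(labels) != X.shape[0]:
        raise ValidationError("labels length must equal number of cells")

    # merge undersized clusters into the nearest big cluster by centroid
    uniq, counts = np.unique(labels, return_counts=True)
    big = uniq[counts >= min_size]
    if big.size == 0:
        big = uniq[counts == counts.max()]
    centroids = {u: X[labels == u].mean(axis=0) for u in uniq}
    relabel = {}
    for u in uniq:
        if u in big:
            relabel[u] = u
        else:
            dists = {b: np.linalg.norm(centroids[u] - centroids[b]) for b in big}
            relabel[u] = min(dists, key=dists.get)
    merged = np.array([relabel[u] for u in labels])

    rows, sizes, names = [], [], []
    for i, u in enumerate(np.unique(merged)):
        mask = merged == u
        rows.append(X[mask].mean(axis=0))
        sizes.append(int(mask.sum()))
        names.append(f"mc{i}")
    return MetaCellMatrix(
        means=pd.DataFrame(np.vstack(rows), index=names, columns=df.columns),
        sizes=pd.Series(sizes, index=names, name="n_cells"),
    )


def gene_gene_correlation(
    metacells: MetaCellMatrix, anchor_gene: str | None = None
):
    """Pearson correlation over meta-cell averages.

    With ``anchor_gene`` given, returns the anchor's correlation with every
    other gene (Series); otherwise the full symmetric gene × gene matrix.
    Constant genes get NaN.
    """
    means = metacells.means
    if len(means) < 3:
        raise ValidationError("need at least 3 meta-cell clusters")
    X = means.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    if anchor_gene is not None:
        if anchor_gene not in means.columns:
            raise ValidationError(f"anchor gene {anchor_gene!r} absent")
        a = Z[:, means.columns.get_loc(anchor_gene)]
        r = Z.T @ a / len(a)
        r[sd == 0] = np.nan
        out = pd.Series(r, index=means.columns, name=f"r_{anchor_gene}")
        if sd[means.columns.get_loc(anchor_gene)] == 0:
            out[:] = np.nan
        return out
    R = Z.T @ Z / Z.shape[0]
    R[sd == 0, :] = np.nan
    R[:, sd == 0] = np.nan
    np.fill_diagonal(R, np.where(sd > 0, 1.0, np.nan))
    return pd.DataFrame(R, index=means.columns, columns=means.columns)


def consensus_anchor_correlates(
    per_cohort: dict[str, pd.Series],
    min_abs_r: float = 0.2,
    rule: str = "same_sign_all",
) -> dict[str, list[str]]:
    """Genes whose anchor correlation is consistent across cohorts.

    A gene qualifies if |r| ≥ ``min_abs_r`` in *every* cohort and the sign is
    identical in all cohorts (``rule='same_sign_all'``); ``rule='threshold'``
    relaxes to the |r| criterion in every cohort only (single-cohort use).
    Returns ``{"positive": [...], "negative": [...]}``.
    """
    if rule not in ("same_sign_all", "threshold"):
        raise ValidationError(f"unknown rule {rule!r}")
    vectors = list(per_cohort.values())
    universe = vectors[0].index
    for v in vectors[1:]:
        universe = universe.intersection(v.index)
    if len(universe) == 0:
        raise ValidationError("cohort vectors share no genes")
    mat = np.column_stack([v.loc[universe].to_numpy(dtype=float) for v in vectors])
    passes = (np.abs(mat) >= min_abs_r) & np.isfinite(mat)
    all_pass = passes.all(axis=1)
    signs = np.sign(mat)
    same_sign = (signs == signs[:, :1]).all(axis=1)
    if rule == "same_sign_all":
        keep = all_pass & same_sign
    else:
        keep = all_pass
    pos = [str(g) for g, k, s in zip(universe, keep, signs[:, 0]) if k and s > 0]
    neg = [str(g) for g, k, s in zip(universe, keep, signs[:, 0]) if k and s < 0]
    return {"positive": pos, "negative": neg}


def bin_smooth_trajectory(
    pseudotime: np.ndarray,
    expr,
    genes: list[str] | None = None,
    n_bins: int = 20,
    window: int = 3,
) -> TrajectoryCurves:
    """Equal-count pseudotime bins, per-bin means, moving-average smoothing.

    Cells are ordered by pseudotime (stable sort, so ties keep input order)
    and split into ``n_bins`` bins whose sizes differ by at most one; the
    smoothed curve is a centered moving average of window ``window`` over the
    bin means with shrunk windows at the endpoints.
    """
    pt = np.asarray(pseudotime, dtype=float)
    if not np.isfinite(pt).all():
        raise ValidationError("pseudotime contains non-finite values")
    df = pd.DataFrame(expr) if not isinstance(expr, pd.DataFrame) else expr
    if len(pt) != len(df):
        raise ValidationError("pseudotime length must equal number of cells")
    if len(pt) < n_bins:
        raise ValidationError(f"need at least {n_bins} cells for {n_bins} bins")
    if genes is not None:
        absent = [g for g in genes if g not in df.columns]
        if absent:
            raise ValidationError(f"genes absent from expression table: {absent}")
        df = df[genes]
    order = np.argsort(pt, kind="stable")
    chunks = np.array_split(order, n_bins)
    X = df.to_numpy(dtype=float)
    means = np.column_stack([X[c].mean(axis=0) for c in chunks])  # genes × bins
    centers = np.array([pt[c].mean() for c in chunks])
    sizes = np.array([len(c) for c in chunks])
    half = window // 2
    smoothed = np.empty_like(means)
    for b in range(n_bins):
        lo, hi = max(0, b - half), min(n_bins, b + half + 1)
        smoothed[:, b] = means[:, lo:hi].mean(axis=1)
    bins = [f"bin{i}" for i in range(n_bins)]
    return TrajectoryCurves(
        bin_centers=centers,
        bin_sizes=sizes,
        means=pd.DataFrame(means, index=df.columns, columns=bins),
        smoothed=pd.DataFrame(smoothed, index=df.columns, columns=bins),
        window=window,
    )
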
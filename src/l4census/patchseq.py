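"""Patch-seq transcriptomic mapping to a reference atlas.

Query cells (cells x genes read counts, held in :class:`anndata.AnnData`)
pass a library-size quality filter, are log2(x+1)-transformed, and are
assigned to reference clusters by maximum Pearson correlation with the
cluster centroids over a most-variable-gene set (intersected by gene name
with the query's gene universe). For visualization, each query cell is
placed on the reference 2-D embedding at the coordinate-wise median
location of its 10 most-correlated reference cells.

Variable-gene selection follows a dropout-based rule: writing mu for the
mean log2 count over counts above a threshold (32 reads) and tau for the
fraction of counts below it, genes across a dataset follow roughly
tau = exp(-1.5 mu + a); the selected genes are those lying clearly above
that curve, tau > exp(-1.5 mu + b) + 0.02, with the offset b found by
binary search so that the requested number of genes is selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ReferenceAtlas",
    "qc_filter",
    "gene_dropout_stats",
    "select_variable_genes",
    "map_to_reference",
    "knn_median_placement",
]

COUNT_THRESHOLD = 32
MIN_CELLS_AT_THRESHOLD = 10
DROPOUT_SLOPE = -1.5
DROPOUT_MARGIN = 0.02


@dataclass
class ReferenceAtlas:
    """Reference transcriptomic atlas.

    centroids: clusters x genes mean log2(x+1) expression (DataFrame with
    cluster labels as the index and gene names as columns).
    reference_cells: optional AnnData of individual reference cells whose
    ``obsm['embedding']`` holds their 2-D embedding coordinates (used for
    the kNN-median placement).
    variable_genes: the atlas's most-variable-gene list.
    """

    centroids: pd.DataFrame
    variable_genes: list
    reference_cells: ad.AnnData | None = None

    def __post_init__(self):
        missing = [g for g in self.variable_genes if g not in self.centroids.columns]
        if missing:
            raise ValueError(f"variable genes absent from centroids: {missing[:5]}...")

    @property
    def cluster_labels(self) -> list:
        return list(self.centroids.index)


def _dense_counts(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if sp.issparse(X):
        X = X.toarray()
    return np.asarray(X, dtype=float)


def qc_filter(adata: ad.AnnData, min_total: int = 1500) -> ad.AnnData:
    """Remove cells whose total count over all genes falls below ``min_total``.

    The removed cell ids are kept in ``uns['qc_removed_cells']`` of the
    returned object.
    """
    if adata.n_obs == 0:
        raise ValueError("empty count matrix")
    totals = np.asarray(_dense_counts(adata).sum(axis=1)).ravel()
    keep = totals >= min_total
    if not keep.any():
        raise ValueError("all cells fall below the library-size threshold")
    out = adata[keep].copy()
    out.uns["qc_removed_cells"] = [str(c) for c in adata.obs_names[~keep]]
    return out


def gene_dropout_stats(
    counts: np.ndarray, threshold: int = COUNT_THRESHOLD, min_cells: int = MIN_CELLS_AT_THRESHOLD
) -> pd.DataFrame:
    """Per-gene (mu, tau) dropout statistics on the prevalence-filtered genes.

    A gene is scored only if it has counts of at least ``threshold`` in at
    least ``min_cells`` cells. mu is the mean log2 count over counts
    strictly above the threshold; tau the fraction of counts strictly below
    it (counts exactly equal to the threshold enter neither statistic's
    numerator, per the literal definitions).
    """
    counts = np.asarray(counts, dtype=float)
    n_at = (counts >= threshold).sum(axis=0)
    passing = np.flatnonzero(n_at >= min_cells)
    mus, taus = [], []
    for j in passing:
        col = counts[:, j]
        above = col > threshold
        mus.append(np.log2(col[above]).mean() if above.any() else np.nan)
        taus.append(float((col < threshold).mean()))
    return pd.DataFrame({"gene_index": passing, "mu": mus, "tau": taus})


def _selected_mask(stats: pd.DataFrame, b: float) -> np.ndarray:
    return (
        stats["tau"].to_numpy()
        > np.exp(DROPOUT_SLOPE * stats["mu"].to_numpy() + b) + DROPOUT_MARGIN
    )


def select_variable_genes(
    adata_or_counts, n_target: int, gene_names=None, threshold: int = COUNT_THRESHOLD
) -> list:
    """Select the ``n_target`` most variable genes by the dropout criterion.

    The number of genes selected is monotonically non-increasing in the
    offset b, so a binary search brackets the target count. When no offset
    yields exactly ``n_target`` (plateaus), the attainable count nearest to
    it is returned, preferring the larger set on ties.
    """
    if n_target <= 0:
        raise ValueError("n_target must be positive")
    if isinstance(adata_or_counts, ad.AnnData):
        counts = _dense_counts(adata_or_counts)
        gene_names = list(adata_or_counts.var_names)
    else:
        counts = np.asarray(adata_or_counts, dtype=float)
        if gene_names is None:
            gene_names = [f"g{j}" for j in range(counts.shape[1])]
    stats = gene_dropout_stats(counts, threshold=threshold)
    stats = stats[~stats["mu"].isna()]
    if n_target > len(stats):
        raise ValueError(
            f"n_target={n_target} exceeds the {len(stats)} genes passing the prevalence filter"
        )

    mu = stats["mu"].to_numpy()
    lo = float(DROPOUT_SLOPE * mu.max() - 10.0)  # selects (almost) everything
    hi = float(DROPOUT_SLOPE * mu.min() + 10.0)  # selects nothing
    while int(_selected_mask(stats, lo).sum()) < n_target and lo > -1e6:
        lo -= 10.0
    while int(_selected_mask(stats, hi).sum()) > 0:
        hi += 10.0

    # binary search for the largest b still selecting >= n_target genes
    for _ in range(200):
        if hi - lo < 1e-9:
            break
        mid = 0.5 * (lo + hi)
        if int(_selected_mask(stats, mid).sum()) >= n_target:
            lo = mid
        else:
            hi = mid
    n_lo = int(_selected_mask(stats, lo).sum())
    n_hi = int(_selected_mask(stats, hi).sum())
    b = lo if abs(n_lo - n_target) <= abs(n_hi - n_target) else hi
    mask = _selected_mask(stats, b)
    idx = stats["gene_index"].to_numpy()[mask]
    return [gene_names[j] for j in sorted(idx)]


def _log2p1(x: np.ndarray) -> np.ndarray:
    return np.log2(x + 1.0)


def _pearson_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Correlation of every row of A with every row of B (shared columns)."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = (A @ B.T) / np.outer(na, nb)
    return C


def map_to_reference(adata: ad.AnnData, atlas: ReferenceAtlas) -> pd.DataFrame:
    """Assign each query cell to the reference cluster of maximal correlation.

    Counts are log2(x+1)-transformed; the correlation runs over the
    intersection (by name) of the atlas's variable genes with the query's
    gene universe. Returns a DataFrame indexed by cell id with the assigned
    cluster, the winning correlation, and the full correlation matrix in
    ``attrs['correlations']``. Zero-variance cells over the gene set are
    flagged unmappable (cluster NA).
    """
    genes = [g for g in atlas.variable_genes if g in set(adata.var_names)]
    if len(genes) < 2:
        raise ValueError("fewer than two atlas genes present in the query")
    q = _log2p1(_dense_counts(adata[:, genes]))
    cent = atlas.centroids[genes].to_numpy(dtype=float)
    C = _pearson_rows(q, cent)
    best = np.nanargmax(np.where(np.isnan(C), -np.inf, C), axis=1)
    unmappable = np.isnan(C).all(axis=1)
    labels = np.array(atlas.cluster_labels, dtype=object)[best]
    corr = C[np.arange(len(best)), best]
    labels = pd.array(labels, dtype=object)
    labels[unmappable] = pd.NA
    out = pd.DataFrame(
        {"cluster": labels, "correlation": np.where(unmappable, np.nan, corr)},
        index=adata.obs_names,
    )
    out.attrs["correlations"] = pd.DataFrame(
        C, index=adata.obs_names, columns=atlas.cluster_labels
    )
    out.attrs["genes_used"] = genes
    return out


def knn_median_placement(adata: ad.AnnData, atlas: ReferenceAtlas, k: int = 10) -> pd.DataFrame:
    """Place each query cell at the coordinate-wise median embedding location
    of its ``k`` most-correlated reference cells.

    Ties in the correlation at rank k are broken deterministically by
    lexicographic reference-cell id.
    """
    if atlas.reference_cells is None:
        raise ValueError("atlas has no reference cells with embedding coordinates")
    ref = atlas.reference_cells
    if ref.n_obs < k:
        raise ValueError(f"need at least k={k} reference cells")
    genes = [g for g in atlas.variable_genes if g in set(adata.var_names)]
    if len(genes) < 2:
        raise ValueError("fewer than two atlas genes present in the query")
    q = _log2p1(_dense_counts(adata[:, genes]))
    r = _log2p1(_dense_counts(ref[:, genes]))
    C = _pearson_rows(q, r)
    emb = np.asarray(ref.obsm["embedding"], dtype=float)
    ref_ids = np.array([str(i) for i in ref.obs_names])
    # sort by (-correlation, reference id): deterministic under ties
    order_ids = np.argsort(ref_ids, kind="stable")
    coords = np.empty((adata.n_obs, 2))
    for i in range(adata.n_obs):
        c = C[i][order_ids]
        top = order_ids[np.argsort(-c, kind="stable")[:k]]
        coords[i] = np.median(emb[top], axis=0)
    return pd.DataFrame(coords, index=adata.obs_names, columns=["embed_1", "embed_2"])
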
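"""Quality control, variable-gene selection, and reference-atlas mapping."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from l4census.patchseq import (
    ReferenceAtlas,
    gene_dropout_stats,
    knn_median_placement,
    map_to_reference,
    qc_filter,
    select_variable_genes,
)
from l4census.synthetic import gen_counts


def _adata(counts, genes=None, cells=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{j}" for j in range(counts.shape[1])]
    cells = cells or [f"c{i}" for i in range(counts.shape[0])]
    return ad.AnnData(
        X=counts,
        obs=pd.DataFrame(index=cells),
        var=pd.DataFrame(index=genes),
    )


class TestQCFilter:
    def test_boundary_is_below_not_at(self):
        adata = _adata(np.array([[1499, 0], [1500, 0], [2000, 5]]))
        out = qc_filter(adata)
        assert out.n_obs == 2
        assert out.uns["qc_removed_cells"] == ["c0"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            qc_filter(_adata(np.zeros((0, 3))))

    def test_seeded_low_depth_cells_removed(self):
        adata, _, _ = gen_counts(seed=1, n_cells=118, low_depth_fraction=4 / 118)
        out = qc_filter(adata)
        assert out.n_obs == 114
        assert len(out.uns["qc_removed_cells"]) == 4


class TestVariableGenes:
    def test_prevalence_filter_excludes_rare_gene(self):
        # gene 0: >=32 in only 9 cells -> excluded before scoring
        counts = np.zeros((20, 2), dtype=int)
        counts[:9, 0] = 100
        counts[:, 1] = 100
        stats = gene_dropout_stats(counts)
        assert 0 not in stats["gene_index"].to_numpy()
        assert 1 in stats["gene_index"].to_numpy()

    def test_high_dropout_gene_preferred(self):
        # A: 100 everywhere (tau=0); B: same mu but expressed in 10 of 12 cells
        counts = np.full((12, 2), 100, dtype=int)
        counts[10:, 1] = 0
        genes = select_variable_genes(counts, 1, gene_names=["A", "B"])
        assert genes == ["B"]

    def test_count_exactly_at_threshold_enters_neither_statistic(self):
        counts = np.full((12, 1), 32, dtype=int)
        stats = gene_dropout_stats(counts)
        # mu over counts > 32 is undefined; tau over counts < 32 is 0
        assert np.isnan(stats["mu"].iloc[0])
        assert stats["tau"].iloc[0] == 0.0

    def test_binary_search_matches_grid_scan(self, rng):
        adata, _, _ = gen_counts(seed=4, n_cells=150, n_genes=200)
        counts = np.asarray(adata.X)
        stats = gene_dropout_stats(counts)
        stats = stats[~stats["mu"].isna()]
        mu, tau = stats["mu"].to_numpy(), stats["tau"].to_numpy()

        def n_selected(b):
            return int((tau > np.exp(-1.5 * mu + b) + 0.02).sum())

        grid = np.linspace(-30, 30, 20001)
        sizes = np.array([n_selected(b) for b in grid])
        assert (np.diff(sizes) <= 0).all()  # monotone in b
        n_target = 50
        genes = select_variable_genes(counts, n_target)
        attainable = sizes[np.argmin(np.abs(sizes - n_target))]
        assert len(genes) == attainable

    def test_selection_order_independent(self):
        adata, _, _ = gen_counts(seed=5, n_cells=100, n_genes=120)
        counts = np.asarray(adata.X)
        names = list(adata.var_names)
        sel = select_variable_genes(counts, 30, gene_names=names)
        perm = np.random.default_rng(1).permutation(counts.shape[0])
        sel2 = select_variable_genes(counts[perm], 30, gene_names=names)
        assert sel == sel2

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            select_variable_genes(np.full((12, 3), 100), 0)


class TestMapping:
    def _toy_atlas(self):
        genes = [f"g{j}" for j in range(6)]
        cent = pd.DataFrame(
            [[5, 0, 0, 4, 1, 2], [0, 5, 1, 0, 4, 2], [1, 1, 5, 2, 0, 4]],
            index=["A", "B", "C"],
            columns=genes,
            dtype=float,
        )
        return ReferenceAtlas(centroids=cent, variable_genes=genes)

    def test_query_equal_to_centroid_maps_with_corr_one(self):
        atlas = self._toy_atlas()
        counts = (2 ** atlas.centroids.loc[["B"]].to_numpy() - 1).round().astype(int)
        res = map_to_reference(_adata(counts, genes=list(atlas.centroids.columns)), atlas)
        assert res["cluster"].iloc[0] == "B"
        assert res["correlation"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_gene_order_permutation_invariant(self):
        atlas = self._toy_atlas()
        genes = list(atlas.centroids.columns)
        counts = (2 ** atlas.centroids.loc[["C"]].to_numpy() - 1).round().astype(int)
        perm = [3, 0, 5, 1, 4, 2]
        shuffled = _adata(counts[:, perm], genes=[genes[j] for j in perm])
        res = map_to_reference(shuffled, atlas)
        assert res["cluster"].iloc[0] == "C"

    def test_zero_variance_cell_flagged_unmappable(self):
        atlas = self._toy_atlas()
        counts = np.full((1, 6), 7)
        res = map_to_reference(_adata(counts, genes=list(atlas.centroids.columns)), atlas)
        assert pd.isna(res["cluster"].iloc[0])

    def test_planted_clusters_recovered(self):
        adata, labels, atlas = gen_counts(seed=0, n_cells=300)
        res = map_to_reference(adata, atlas)
        acc = (res["cluster"].to_numpy() == labels).mean()
        assert acc >= 0.95

    def test_correlations_bounded(self):
        adata, _, atlas = gen_counts(seed=2, n_cells=60)
        res = map_to_reference(adata, atlas)
        C = res.attrs["correlations"].to_numpy()
        assert np.nanmin(C) >= -1 - 1e-12 and np.nanmax(C) <= 1 + 1e-12


class TestPlacement:
    def _atlas_with_cells(self, seed=0):
        return gen_counts(seed=seed, n_cells=50)

    def test_unanimous_neighbours_place_exactly(self):
        genes = [f"g{j}" for j in range(5)]
        rng = np.random.default_rng(0)
        ref_counts = rng.integers(0, 50, size=(12, 5))
        ref = _adata(ref_counts, genes=genes, cells=[f"r{i}" for i in range(12)])
        ref.obsm["embedding"] = np.tile([2.5, -1.5], (12, 1))
        cent = pd.DataFrame(np.log2(ref_counts[:3] + 1.0), index=list("ABC"), columns=genes)
        atlas = ReferenceAtlas(centroids=cent, variable_genes=genes, reference_cells=ref)
        q = _adata(rng.integers(0, 50, size=(1, 5)), genes=genes)
        coords = knn_median_placement(q, atlas, k=10)
        np.testing.assert_allclose(coords.iloc[0].to_numpy(), [2.5, -1.5])

    def test_k_equal_one_uses_nearest_neighbour(self):
        adata, labels, atlas = self._atlas_with_cells()
        coords = knn_median_placement(adata[:3], atlas, k=1)
        # brute force: the single most-correlated reference cell
        from l4census.patchseq import _dense_counts, _log2p1, _pearson_rows

        genes = [g for g in atlas.variable_genes if g in set(adata.var_names)]
        q = _log2p1(_dense_counts(adata[:3, genes]))
        r = _log2p1(_dense_counts(atlas.reference_cells[:, genes]))
        C = _pearson_rows(q, r)
        for i in range(3):
            best = np.argmax(C[i])
            np.testing.assert_allclose(
                coords.iloc[i].to_numpy(), atlas.reference_cells.obsm["embedding"][best]
            )

    def test_matches_brute_force_median(self):
        adata, labels, atlas = self._atlas_with_cells(seed=3)
        k = 10
        coords = knn_median_placement(adata[:5], atlas, k=k)
        from l4census.patchseq import _dense_counts, _log2p1, _pearson_rows

        genes = [g for g in atlas.variable_genes if g in set(adata.var_names)]
        q = _log2p1(_dense_counts(adata[:5, genes]))
        r = _log2p1(_dense_counts(atlas.reference_cells[:, genes]))
        C = _pearson_rows(q, r)
        emb = atlas.reference_cells.obsm["embedding"]
        for i in range(5):
            top = np.argsort(-C[i], kind="stable")[:k]
            np.testing.assert_allclose(
                coords.iloc[i].to_numpy(), np.median(emb[top], axis=0), atol=1e-9
            )

    def test_placements_land_in_true_cluster_blob(self):
        adata, labels, atlas = gen_counts(seed=6, n_cells=200)
        coords = knn_median_placement(adata, atlas, k=10).to_numpy()
        emb = atlas.reference_cells.obsm["embedding"]
        refclu = atlas.reference_cells.obs["cluster"].to_numpy()
        hits = 0
        for i, lab in enumerate(labels):
            blob = emb[refclu == lab]
            lo, hi = blob.min(axis=0), blob.max(axis=0)
            hits += bool((coords[i] >= lo).all() and (coords[i] <= hi).all())
        assert hits / len(labels) >= 0.90
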
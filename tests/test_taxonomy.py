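"""Normalization, HVG, clustering, gating, marker ranking, class merge."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from striatax import synthetic, taxonomy
from striatax.config import QCThresholds, TaxonomyParams
from striatax.containers import CountMatrix

from conftest import small_config


def make_counts(X, genes=None, cells=None, meta=None):
    X = np.asarray(X)
    genes = genes or [f"G{i}" for i in range(X.shape[1])]
    cells = cells or [f"c{i}" for i in range(X.shape[0])]
    return CountMatrix(
        sp.csr_matrix(X), np.asarray(cells, dtype=object),
        np.asarray(genes, dtype=object),
        meta if meta is not None else pd.DataFrame(index=cells),
    )


class TestNormalizeLog:
    def test_closed_form(self):
        counts = make_counts([[2, 8], [5, 5]])
        norm = taxonomy.normalize_log(counts, target_sum=10.0)
        X = norm.values.toarray()
        np.testing.assert_allclose(X[0], [np.log1p(2.0), np.log1p(8.0)])
        np.testing.assert_allclose(X[1], [np.log1p(5.0), np.log1p(5.0)])

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        A = rng.poisson(5, size=(20, 30))
        a = taxonomy.normalize_log(make_counts(A)).values.toarray()
        b = taxonomy.normalize_log(make_counts(A * 3)).values.toarray()
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_zero_total_cell_rejected(self):
        counts = make_counts([[0, 0], [1, 2]])
        with pytest.raises(ValueError, match="zero total"):
            taxonomy.normalize_log(counts)

    def test_zero_entries_stay_zero(self):
        counts = make_counts([[0, 10], [3, 0]])
        X = taxonomy.normalize_log(counts).values.toarray()
        assert X[0, 0] == 0.0 and X[1, 1] == 0.0


class TestGeneExclusion:
    def test_categories(self):
        genes = ["MT-1", "RPS4", "RPL3", "MRPS2", "XIST", "GAD1", "mrpl44"]
        mask = taxonomy.gene_exclusion_mask(np.asarray(genes))
        np.testing.assert_array_equal(
            mask, [True, True, True, True, True, False, True]
        )

    def test_selective_exclude(self):
        genes = np.asarray(["MT-1", "RPS4", "XIST"])
        mask = taxonomy.gene_exclusion_mask(genes, exclude={"mito"})
        np.testing.assert_array_equal(mask, [True, False, False])


class TestSelectHVG:
    def _norm(self, X, genes):
        return taxonomy.normalize_log(make_counts(X, genes=genes))

    def test_constant_genes_never_selected(self):
        # a gene with zero variance in normalized space gets -inf dispersion
        rng = np.random.default_rng(1)
        X = rng.poisson(5, size=(50, 10)).astype(float)
        X[:, 3] = 4.0
        norm = taxonomy.NormalizedMatrix(
            sp.csr_matrix(X),
            np.array([f"c{i}" for i in range(50)], dtype=object),
            np.array([f"G{i}" for i in range(10)], dtype=object),
        )
        hvgs = taxonomy.select_hvg(norm, 9)
        assert "G3" not in hvgs

    def test_excluded_categories_never_selected(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(5, size=(50, 6))
        X[:, 0] = rng.poisson(50, size=50)  # highly variable but mito
        genes = ["MT-1", "RPS9", "XIST", "A", "B", "C"]
        hvgs = taxonomy.select_hvg(self._norm(X, genes), 3)
        assert set(hvgs) <= {"A", "B", "C"}

    def test_planted_markers_recovered(self):
        # with no filler heterogeneity the only population signal is the
        # on/off markers: they must dominate the HVG ranking. A large
        # filler universe keeps the mean-quantile bins from being filled
        # by the markers themselves (which would z-score them away).
        cfg = small_config(
            n_pops=2, n_genes=2000, cells_per_sample=300, heterogeneity=0.0
        )
        counts, _ = synthetic.generate_dataset(cfg)
        norm = taxonomy.normalize_log(counts)
        hvgs = set(taxonomy.select_hvg(norm, 40))
        markers = {g for p in cfg.populations for g in p.marker_genes}
        assert len(markers & hvgs) >= 15  # 20 markers total

    def test_requested_count_and_uniqueness(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(3, size=(40, 30))
        hvgs = taxonomy.select_hvg(self._norm(X, None), 12)
        assert len(hvgs) == 12 and len(set(hvgs)) == 12

    def test_too_many_requested(self):
        rng = np.random.default_rng(4)
        X = rng.poisson(3, size=(10, 5))
        with pytest.raises(ValueError, match="eligible"):
            taxonomy.select_hvg(self._norm(X, None), 6)


class TestEmbedCluster:
    def test_two_population_recovery(self):
        cfg = small_config(n_pops=2, n_genes=300, cells_per_sample=300)
        counts, truth = synthetic.generate_dataset(cfg)
        norm = taxonomy.normalize_log(counts)
        hvgs = taxonomy.select_hvg(norm, 100)
        labels = taxonomy.embed_cluster(norm, hvgs, 10, 0.2, seed=0)
        pop = truth.set_index("cell_id").loc[norm.cell_ids, "population"]
        assert adjusted_rand_score(pop, labels) == 1.0

    def test_determinism(self):
        cfg = small_config(n_pops=2, n_genes=200, cells_per_sample=150)
        counts, _ = synthetic.generate_dataset(cfg)
        norm = taxonomy.normalize_log(counts)
        hvgs = taxonomy.select_hvg(norm, 80)
        a = taxonomy.embed_cluster(norm, hvgs, 10, 0.5, seed=7)
        b = taxonomy.embed_cluster(norm, hvgs, 10, 0.5, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_labels_ordered_by_size(self):
        cfg = small_config(n_pops=3, n_genes=400, cells_per_sample=300)
        # unbalanced populations
        cfg.populations[0].proportion_by_region = {"CN": 0.6, "Pu": 0.6}
        cfg.populations[1].proportion_by_region = {"CN": 0.3, "Pu": 0.3}
        cfg.populations[2].proportion_by_region = {"CN": 0.1, "Pu": 0.1}
        counts, _ = synthetic.generate_dataset(cfg)
        norm = taxonomy.normalize_log(counts)
        hvgs = taxonomy.select_hvg(norm, 100)
        labels = taxonomy.embed_cluster(norm, hvgs, 10, 0.5, seed=0)
        sizes = pd.Series(labels).value_counts().sort_index()
        assert list(sizes) == sorted(sizes, reverse=True)

    def test_too_few_cells(self):
        rng = np.random.default_rng(0)
        counts = make_counts(rng.poisson(5, size=(10, 20)))
        norm = taxonomy.normalize_log(counts)
        with pytest.raises(ValueError, match="k-NN"):
            taxonomy.embed_cluster(norm, list(norm.gene_names[:5]), 3, 1.0)


class TestMarkerGating:
    def _norm_with_clusters(self, cluster_gene_means, genes):
        """30 cells per cluster with Poisson counts at the given means.

        A constant high-count background gene keeps totals positive so
        that silent genes remain exactly zero after normalization.
        """
        rng = np.random.default_rng(9)
        blocks, labels = [], []
        for k, means in enumerate(cluster_gene_means):
            blocks.append(rng.poisson(np.asarray(means) * 40, size=(30, len(genes))))
            labels += [k] * 30
        X = np.vstack(blocks)
        X = np.hstack([X, np.full((X.shape[0], 1), 1000)])
        counts = make_counts(X, genes=list(genes) + ["BACKGROUND"])
        return taxonomy.normalize_log(counts), np.asarray(labels)

    def test_label_clusters_by_markers(self):
        genes = ["AQP4", "CSF1R", "MEG3"]
        panel = {"astrocyte": ["AQP4"], "microglia": ["CSF1R"], "neuron": ["MEG3"]}
        norm, labels = self._norm_with_clusters(
            [[5, 0, 0], [0, 5, 0], [0, 0, 5]], genes
        )
        out = taxonomy.label_clusters_by_markers(norm, labels, panel)
        assert out == {0: "astrocyte", 1: "microglia", 2: "neuron"}

    def test_ambiguous_is_unassigned(self):
        genes = ["AQP4", "CSF1R"]
        panel = {"astrocyte": ["AQP4"], "microglia": ["CSF1R"]}
        norm, labels = self._norm_with_clusters([[5, 5], [0, 5]], genes)
        out = taxonomy.label_clusters_by_markers(norm, labels, panel)
        assert out[0] == "unassigned" and out[1] == "microglia"

    def test_gate_gad_positive_passes(self):
        genes = list(taxonomy.POSITIVE_GATE) + list(taxonomy.NEGATIVE_GATE)
        # cluster 0: GAD1 high, all MSN markers silent -> interneuron
        # cluster 1: GAD1 high but PPP1R1B high -> excluded
        # cluster 2: CHAT only -> included (cholinergic)
        rows = [
            [5, 0, 0, 0, 0, 0, 0, 0],
            [5, 0, 0, 5, 0, 0, 0, 0],
            [0, 0, 5, 0, 0, 0, 0, 0],
        ]
        norm, labels = TestMarkerGating()._norm_with_clusters(rows, genes)
        kept = set(taxonomy.select_interneurons(norm, labels))
        kept_clusters = set(labels[np.isin(norm.cell_ids, list(kept))])
        assert kept_clusters == {0, 2}

    def test_gate_all_negative_required(self):
        genes = list(taxonomy.POSITIVE_GATE) + list(taxonomy.NEGATIVE_GATE)
        # GAD2 positive but RORB (excitatory) high -> excluded
        rows = [[0, 5, 0, 0, 0, 0, 0, 5]]
        norm, labels = self._norm_with_clusters(rows, genes)
        # need >= 2 clusters for a meaningful test; add clean one
        rows.append([0, 5, 0, 0, 0, 0, 0, 0])
        norm, labels = self._norm_with_clusters(rows, genes)
        kept = set(taxonomy.select_interneurons(norm, labels))
        kept_clusters = set(labels[np.isin(norm.cell_ids, list(kept))])
        assert kept_clusters == {1}


class TestNeuronRefilter:
    def test_boundaries(self):
        t = QCThresholds()
        n_genes_total = 13000
        rows = np.zeros((4, n_genes_total), dtype=int)
        rows[0, :3000] = 2  # 6000 UMIs, 3000 genes: kept (at both floors)
        rows[1, :3000] = 1  # 3000 UMIs < 5000: removed
        rows[1, 0] += 1999  # 4999 UMIs: still removed (strict floor at 5000)
        rows[2, :12000] = 1  # 12000 genes: kept (at ceiling), 12000 UMIs
        rows[3, :12001] = 1  # 12001 genes: removed
        counts = make_counts(rows)
        kept = set(taxonomy.neuron_quality_refilter(counts, counts.cell_ids, t))
        assert kept == {"c0", "c2"}


class TestRankMarkerGenes:
    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.poisson(3, size=(40, 8)).astype(float)
        X[:20, 0] += rng.poisson(6, size=20)  # planted marker for group A
        labels = np.array(["A"] * 20 + ["B"] * 20)
        norm = taxonomy.NormalizedMatrix(
            sp.csr_matrix(X), np.array([f"c{i}" for i in range(40)], dtype=object),
            np.array([f"G{i}" for i in range(8)], dtype=object),
        )
        res = taxonomy.rank_marker_genes(norm, labels)
        a = res[res["group"] == "A"].set_index("gene")
        for j in range(8):
            col = X[:, j]
            if np.ptp(col) == 0:
                assert a.loc[f"G{j}", "pval"] == 1.0
                continue
            ref = stats.mannwhitneyu(
                col[:20], col[20:], alternative="two-sided", method="asymptotic",
                use_continuity=False,
            ).pvalue
            assert a.loc[f"G{j}", "pval"] == pytest.approx(ref, rel=1e-6)

    def test_planted_marker_ranks_first(self):
        rng = np.random.default_rng(6)
        X = rng.poisson(2, size=(60, 20)).astype(float)
        X[:30, 7] += 8
        labels = np.array(["A"] * 30 + ["B"] * 30)
        norm = taxonomy.NormalizedMatrix(
            sp.csr_matrix(X), np.array([f"c{i}" for i in range(60)], dtype=object),
            np.array([f"G{i}" for i in range(20)], dtype=object),
        )
        res = taxonomy.rank_marker_genes(norm, labels)
        top = res[res["group"] == "A"].iloc[0]
        assert top["gene"] == "G7" and top["log2_fold"] > 0

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(7)
        X = rng.poisson(5, size=(100, 200)).astype(float)
        labels = np.array(["A"] * 50 + ["B"] * 50)
        norm = taxonomy.NormalizedMatrix(
            sp.csr_matrix(X), np.array([f"c{i}" for i in range(100)], dtype=object),
            np.array([f"G{i}" for i in range(200)], dtype=object),
        )
        res = taxonomy.rank_marker_genes(norm, labels)
        p = res[res["group"] == "A"]["pval"].to_numpy()
        assert 0.01 < (p < 0.05).mean() < 0.12

    def test_small_group_rejected(self):
        X = np.ones((5, 3))
        norm = taxonomy.NormalizedMatrix(
            sp.csr_matrix(X), np.array([f"c{i}" for i in range(5)], dtype=object),
            np.array(["a", "b", "c"], dtype=object),
        )
        with pytest.raises(ValueError, match="fewer than 3"):
            taxonomy.rank_marker_genes(norm, np.array(["A", "A", "A", "A", "B"]))


class TestBHAdjust:
    def test_textbook_stepup(self):
        p = np.array([0.01, 0.04, 0.03, 0.005])
        # sorted: .005 .01 .03 .04 -> *4/k: .02 .02 .04 .04 -> monotone
        out = taxonomy._bh_adjust(p)
        np.testing.assert_allclose(out, [0.02, 0.04, 0.04, 0.02])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_matches_statsmodels(self, ps):
        from statsmodels.stats.multitest import multipletests

        p = np.asarray(ps)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(taxonomy._bh_adjust(p), ref, atol=1e-12)


def _profiles_with_correlation(r, n_genes=200, seed=0):
    """Two cell groups whose mean profiles have Pearson r ~exactly~ r."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n_genes)
    b = rng.normal(size=n_genes)
    a = (a - a.mean()) / a.std()
    b = (b - b.mean()) / b.std()
    b = b - (a @ b / n_genes) * a  # orthogonalize
    b = (b - b.mean()) / b.std()
    c = r * a + np.sqrt(1 - r**2) * b
    return a, c


class TestMergeSubclasses:
    def _norm_from_profiles(self, profiles, n_cells=12):
        """Cells that exactly repeat each group's profile (no noise)."""
        rows, labels, cells = [], [], []
        for k, prof in enumerate(profiles):
            shifted = prof - prof.min() + 0.1  # nonneg "expression"
            for i in range(n_cells):
                rows.append(shifted)
                labels.append(k)
                cells.append(f"g{k}c{i}")
        X = np.asarray(rows)
        norm = taxonomy.NormalizedMatrix(
            sp.csr_matrix(X), np.asarray(cells, dtype=object),
            np.asarray([f"G{i}" for i in range(X.shape[1])], dtype=object),
        )
        return norm, pd.Series(labels, index=cells, name="subclass")

    def test_threshold_is_strict(self):
        # r = 0.60 > 0.49 merges; r = 0.30 < 0.49 stays split
        a, c = _profiles_with_correlation(0.60)
        norm, labels = self._norm_from_profiles([a, c])
        cls, corr, _, _ = taxonomy.merge_subclasses(norm, labels, 0.49)
        assert corr.iloc[0, 1] == pytest.approx(0.60, abs=1e-9)
        assert cls.nunique() == 1

        a, c = _profiles_with_correlation(0.30)
        norm, labels = self._norm_from_profiles([a, c])
        cls, _, _, _ = taxonomy.merge_subclasses(norm, labels, 0.49)
        assert cls.nunique() == 2

    def test_exactly_at_threshold_not_merged(self):
        a, c = _profiles_with_correlation(0.49)
        norm, labels = self._norm_from_profiles([a, c])
        cls, corr, _, _ = taxonomy.merge_subclasses(norm, labels, 0.49)
        assert corr.iloc[0, 1] == pytest.approx(0.49, abs=1e-9)
        assert cls.nunique() == 2

    def test_components_match_networkx_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(11)
        profs = [rng.normal(size=100) for _ in range(6)]
        # make pairs (0,1) and (2,3) strongly correlated
        profs[1] = profs[0] + rng.normal(scale=0.1, size=100)
        profs[3] = profs[2] + rng.normal(scale=0.1, size=100)
        norm, labels = self._norm_from_profiles(profs)
        cls, corr, _, _ = taxonomy.merge_subclasses(norm, labels, 0.49)

        G = nx.Graph()
        G.add_nodes_from(range(6))
        C = corr.to_numpy()
        for i in range(6):
            for j in range(i + 1, 6):
                if C[i, j] > 0.49:
                    G.add_edge(i, j)
        expected_groups = {frozenset(c) for c in nx.connected_components(G)}
        got_groups = {
            frozenset(labels.index.to_series().groupby(cls).groups[k].map(labels).unique())
            for k in cls.unique()
        }
        got_groups = {
            frozenset(labels[cls == k].unique()) for k in cls.unique()
        }
        assert got_groups == expected_groups

    def test_class_named_after_largest_subclass(self):
        a, c = _profiles_with_correlation(0.9)
        rows, labels, cells = [], [], []
        for k, prof, n in ((0, a, 5), (1, c, 20)):
            shifted = prof - prof.min() + 0.1
            for i in range(n):
                rows.append(shifted)
                labels.append(k)
                cells.append(f"g{k}c{i}")
        norm = taxonomy.NormalizedMatrix(
            sp.csr_matrix(np.asarray(rows)), np.asarray(cells, dtype=object),
            np.asarray([f"G{i}" for i in range(len(a))], dtype=object),
        )
        cls, _, _, _ = taxonomy.merge_subclasses(
            norm, pd.Series(labels, index=cells), 0.49
        )
        assert set(cls.unique()) == {"1"}

    def test_coarsening_invariant(self):
        # lowering the threshold can only reduce the number of classes
        rng = np.random.default_rng(13)
        profs = [rng.normal(size=150) for _ in range(5)]
        profs[1] = 0.7 * profs[0] + 0.7 * rng.normal(size=150)
        norm, labels = self._norm_from_profiles(profs)
        n_at = []
        for thr in (0.9, 0.5, 0.2, -0.5):
            cls, _, _, _ = taxonomy.merge_subclasses(norm, labels, thr)
            n_at.append(cls.nunique())
        assert n_at == sorted(n_at, reverse=True)

    def test_newick_contains_all_subclasses(self):
        rng = np.random.default_rng(14)
        profs = [rng.normal(size=80) for _ in range(4)]
        norm, labels = self._norm_from_profiles(profs)
        _, _, Z, newick = taxonomy.merge_subclasses(norm, labels, 0.49)
        assert Z.shape == (3, 4)
        for s in ("0", "1", "2", "3"):
            assert s in newick

    def test_clique_mode_splits_non_clique_chain(self):
        # chain 0-1-2 where corr(0,2) < thr: components give 1 class,
        # cliques give 2
        rng = np.random.default_rng(15)
        base = rng.normal(size=400)
        n1 = rng.normal(size=400)
        p0 = base
        p1 = 0.8 * base + 0.6 * n1
        p2 = n1
        norm, labels = self._norm_from_profiles([p0, p1, p2])
        _, corr, _, _ = taxonomy.merge_subclasses(norm, labels, 0.49)
        C = corr.to_numpy()
        assert C[0, 1] > 0.49 and C[1, 2] > 0.49 and C[0, 2] < 0.49
        comp, _, _, _ = taxonomy.merge_subclasses(norm, labels, 0.49, "components")
        cliq, _, _, _ = taxonomy.merge_subclasses(norm, labels, 0.49, "clique")
        assert comp.nunique() == 1 and cliq.nunique() == 2


class TestSubclassClustering:
    def test_posthoc_gate_removes_msn_like_cluster(self):
        cfg = small_config(n_pops=2, n_genes=300, cells_per_sample=200)
        cfg.populations[0].marker_genes = list(cfg.populations[0].marker_genes) + [
            "PPP1R1B"
        ]
        counts, truth = synthetic.generate_dataset(cfg)
        norm = taxonomy.normalize_log(counts)
        with pytest.warns(UserWarning, match="post-hoc gate"):
            labels = taxonomy.subclass_clustering(
                norm, TaxonomyParams(subclass_n_hvg=100, subclass_n_pcs=10), seed=0
            )
        pop = truth.set_index("cell_id")["population"]
        assert set(pop.loc[labels.index]) == {"P1"}

    def test_too_few_cells(self):
        rng = np.random.default_rng(0)
        counts = make_counts(rng.poisson(5, size=(50, 30)))
        norm = taxonomy.normalize_log(counts)
        with pytest.raises(ValueError, match="100"):
            taxonomy.subclass_clustering(norm)
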
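"""Classification ladder tests: normalization through merging and panels."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

import striatax as st
from striatax import taxonomy as tax
from striatax.qc import QCThresholds

from conftest import make_matrix


# ----------------------------------------------------------------------
# normalization
# ----------------------------------------------------------------------
class TestNormalizeLog:
    def test_worked_example(self):
        m = make_matrix(np.array([[1, 1, 2]]))
        norm = tax.normalize_log(m)
        np.testing.assert_allclose(
            norm.X.toarray()[0], np.log1p([2500, 2500, 5000]))

    def test_cell_already_at_target_sum(self):
        m = make_matrix(np.array([[4000, 6000]]))
        norm = tax.normalize_log(m)
        np.testing.assert_allclose(norm.X.toarray()[0], np.log1p([4000, 6000]))

    def test_proportional_cells_identical(self):
        m = make_matrix(np.array([[1, 2, 3], [10, 20, 30]]))
        norm = tax.normalize_log(m).X.toarray()
        np.testing.assert_allclose(norm[0], norm[1])


# ----------------------------------------------------------------------
# HVG selection
# ----------------------------------------------------------------------
class TestSelectHVG:
    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, size=(200, 10))
        counts[:, 3] = 5  # constant in raw counts, low dispersion normalized
        m = make_matrix(counts)
        norm = tax.normalize_log(m)
        top = tax.select_hvg(norm, 3)
        assert "g3" not in top

    def test_planted_bimodal_gene_top_ranked(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5, size=(400, 20))
        counts[:200, 7] = rng.poisson(60, size=200)  # strongly bimodal
        m = make_matrix(counts)
        norm = tax.normalize_log(m)
        assert tax.select_hvg(norm, 1) == ["g7"]

    def test_flagged_gene_excluded(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(5, size=(300, 10))
        counts[:150, 0] = rng.poisson(80, size=150)
        m = make_matrix(counts, mito=[True] + [False] * 9)
        norm = tax.normalize_log(m)
        assert "g0" not in tax.select_hvg(norm, 5)

    def test_requesting_too_many_raises(self):
        m = make_matrix(np.ones((60, 4), dtype=int))
        norm = tax.normalize_log(m)
        with pytest.raises(ValueError):
            tax.select_hvg(norm, 10)


# ----------------------------------------------------------------------
# clustering
# ----------------------------------------------------------------------
@pytest.fixture(scope="module")
def two_blob_norm():
    cfg = st.simulate.preset_taxonomy_config(
        n_donors=1, regions=("CN",), cells_per_sample=1000, n_genes=400,
        n_classes=2, seed=8)
    # restrict class tree to one subclass per class -> two clean blobs
    for c in cfg.class_tree:
        c.subclasses = c.subclasses[:1]
    matrix, truth = st.simulate.simulate_dataset(cfg)
    return tax.normalize_log(matrix), truth


class TestEmbedAndCluster:
    def test_two_blobs_perfectly_recovered(self, two_blob_norm):
        norm, truth = two_blob_norm
        clusters = tax.embed_and_cluster(norm, n_pcs=10, resolution=0.2, seed=0)
        assert len(set(clusters)) == 2
        assert adjusted_rand_score(truth.cells["class"], clusters) == 1.0

    def test_low_resolution_single_cluster(self):
        # connected data (one population): resolution -> 0 gives one community
        cfg = st.simulate.preset_taxonomy_config(
            n_donors=1, regions=("CN",), cells_per_sample=400, n_genes=300,
            n_classes=1, seed=12)
        cfg.class_tree[0].subclasses = cfg.class_tree[0].subclasses[:1]
        matrix, _ = st.simulate.simulate_dataset(cfg)
        norm = tax.normalize_log(matrix)
        clusters = tax.embed_and_cluster(norm, n_pcs=10, resolution=1e-4, seed=0)
        assert len(set(clusters)) == 1

    def test_deterministic(self, two_blob_norm):
        norm, _ = two_blob_norm
        c1 = tax.embed_and_cluster(norm, n_pcs=10, resolution=0.5, seed=3)
        c2 = tax.embed_and_cluster(norm, n_pcs=10, resolution=0.5, seed=3)
        np.testing.assert_array_equal(c1, c2)

    def test_too_few_cells_raises(self):
        m = make_matrix(np.ones((5, 10), dtype=int))
        with pytest.raises(ValueError):
            tax.embed_and_cluster(tax.normalize_log(m), n_pcs=2, resolution=1.0, seed=0)


# ----------------------------------------------------------------------
# annotation / neuron refinement / interneuron selection
# ----------------------------------------------------------------------
class TestAnnotateClusters:
    def test_planted_types_all_labeled(self, qc_sim):
        _, matrix, truth = qc_sim
        singlets = ~truth.cells["doublet"].to_numpy()
        sub = matrix.subset_cells(singlets)
        true_cls = truth.cells.loc[singlets, "class"].to_numpy()
        codes = pd.factorize(true_cls)[0]
        labels = tax.annotate_clusters(sub, codes)
        for code, name in labels.items():
            majority = pd.Series(true_cls[codes == code]).mode()[0]
            assert name == majority

    def test_all_zero_scores_lowest_name(self):
        m = make_matrix(np.zeros((20, 4), dtype=int),
                        gene_names=["AQP4", "CSF1R", "MBP", "MEG3"])
        labels = tax.annotate_clusters(m, np.zeros(20, dtype=int))
        assert labels[0] == "Astrocytes"  # deterministic tie-break by name


class TestRefineNeurons:
    def make(self, umi, genes):
        r = np.zeros(20000, dtype=int)
        r[: genes - 1] = 1
        r[genes - 1] = umi - (genes - 1)
        return r

    def test_depth_rules(self):
        rows = np.array([
            self.make(4999, 3500),   # too few UMIs -> discarded
            self.make(5000, 3000),   # boundary -> kept
            self.make(9000, 2999),   # too few genes
            self.make(20000, 12001),  # too many genes
            self.make(9000, 12000),  # boundary high -> kept
        ])
        m = make_matrix(rows)
        labels = np.array(["Neurons"] * 4 + ["Astrocytes"])
        keep = tax.refine_neurons(m, labels)
        assert keep.tolist() == [False, True, False, False, False]

    def test_glia_always_excluded(self):
        m = make_matrix(np.array([self.make(9000, 5000)]))
        assert not tax.refine_neurons(m, np.array(["Astrocytes"])).any()


class TestSelectInterneurons:
    @pytest.fixture
    def neuron_mix(self):
        from striatax.simulate import ClassSpec, SimulationConfig, SubclassSpec

        def cls(name, markers, n_extra):
            extras = [f"GENE{900 + n_extra + i:05d}" for i in range(10)]
            return ClassSpec(name=name, markers=markers + extras,
                             effect=np.log(30.0),
                             subclasses=[SubclassSpec(name=f"{name}_1")])

        tree = [
            cls("Interneuron", ["GAD1", "GAD2"], 0),
            cls("MSN", ["PPP1R1B", "DRD1", "DRD2", "MEIS2", "GAD1", "GAD2"], 10),
            cls("Excitatory", ["RORB", "SLC17A7"], 20),
        ]
        cfg = SimulationConfig(
            n_donors=1, regions=["CN"], cells_per_sample=1200, n_genes=500,
            class_tree=tree,
            composition={"CN": {"Interneuron": 0.3, "MSN": 0.5, "Excitatory": 0.2}},
            baseline_mean=3.0, nb_dispersion=0.1, seed=33,
        )
        return st.simulate.simulate_dataset(cfg)

    def test_planted_mixture_recall(self, neuron_mix):
        matrix, truth = neuron_mix
        norm = tax.normalize_log(matrix)
        codes = pd.factorize(truth.cells["class"])[0]
        mask = tax.select_interneurons(matrix, codes, normalized=norm)
        is_in = (truth.cells["class"] == "Interneuron").to_numpy()
        recall = mask[is_in].mean()
        assert recall >= 0.95
        # MSN clusters express GAD genes too but must be rejected
        assert mask[(truth.cells["class"] == "MSN").to_numpy()].mean() == 0.0
        assert mask[(truth.cells["class"] == "Excitatory").to_numpy()].mean() == 0.0


# ----------------------------------------------------------------------
# marker ranking
# ----------------------------------------------------------------------
class TestRankMarkers:
    def test_exact_p_for_tiny_groups(self):
        counts = np.array([[1], [2], [3], [4]])
        m = make_matrix(counts)
        norm = tax.normalize_log(m)
        norm.X = m.X.astype(float)  # use raw values directly for the oracle
        res = tax.rank_markers_wilcoxon(norm, np.array(["a", "a", "b", "b"]))
        assert np.allclose(res["p"], 2 / 6)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(8, size=(60, 1000))
        m = make_matrix(counts)
        norm = tax.normalize_log(m)
        groups = np.array(["a"] * 30 + ["b"] * 30)
        res = tax.rank_markers_wilcoxon(norm, groups)
        p = res.loc[res["group"] == "a", "p"].to_numpy()
        ks = sps.kstest(p, "uniform").statistic
        assert ks < 0.06

    def test_exclusive_gene_is_top_marker(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(5, size=(100, 30))
        counts[:50, 12] = 0
        counts[50:, 12] = 40  # expressed only in group b
        m = make_matrix(counts)
        norm = tax.normalize_log(m)
        groups = np.array(["a"] * 50 + ["b"] * 50)
        res = tax.rank_markers_wilcoxon(norm, groups)
        b = res[res["group"] == "b"]
        top = b.sort_values(["p", "gene"]).iloc[0]
        best_lfc = b.loc[b["log2_fc"].idxmax(), "gene"]
        assert top["gene"] == "g12" or best_lfc == "g12"
        assert b.set_index("gene").loc["g12", "log2_fc"] > 2

    def test_group_size_validation(self):
        m = make_matrix(np.ones((3, 4), dtype=int))
        norm = tax.normalize_log(m)
        with pytest.raises(ValueError):
            tax.rank_markers_wilcoxon(norm, np.array(["a", "a", "b"]))


# ----------------------------------------------------------------------
# merging and dendrogram
# ----------------------------------------------------------------------
def correlated_groups_matrix(target_corr, n_cells_per=30, n_genes=4000, seed=0):
    """Cells whose group centroids have approximately the given correlations."""
    rng = np.random.default_rng(seed)
    names = sorted(target_corr.keys()) if isinstance(target_corr, dict) else None
    C = target_corr
    L = np.linalg.cholesky(C + 1e-9 * np.eye(len(C)))
    base = rng.standard_normal((len(C), n_genes))
    centroids = L @ base  # rows correlate approximately per C
    cells, groups = [], []
    for gi in range(len(C)):
        for _ in range(n_cells_per):
            cells.append(centroids[gi] + 0.01 * rng.standard_normal(n_genes))
            groups.append(f"t{gi}")
    X = np.array(cells)
    X -= X.min()  # keep values nonnegative like normalized expression
    m = make_matrix(np.zeros((len(cells), n_genes), dtype=int))
    m.X = __import__("scipy.sparse", fromlist=["csr_matrix"]).csr_matrix(X)
    return m, np.array(groups)


class TestMergeByCorrelation:
    def test_rule_application(self):
        C = np.array([[1.0, 0.6, 0.2],
                      [0.6, 1.0, 0.3],
                      [0.2, 0.3, 1.0]])
        m, groups = correlated_groups_matrix(C)
        merge_map, corr = tax.merge_by_correlation(m, groups, threshold=0.49)
        assert merge_map["t0"] == merge_map["t1"]
        assert merge_map["t2"] != merge_map["t0"]

    def test_exact_threshold_not_merged(self):
        C = np.array([[1.0, 0.6], [0.6, 1.0]])
        m, groups = correlated_groups_matrix(C, seed=3)
        _, corr = tax.merge_by_correlation(m, groups)
        r = corr.loc["t0", "t1"]
        # strict inequality: merging at threshold == r must NOT join them
        merge_map, _ = tax.merge_by_correlation(m, groups, threshold=r)
        assert merge_map["t0"] != merge_map["t1"]

    def test_threshold_minus_one_single_class(self):
        C = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        m, groups = correlated_groups_matrix(C, seed=1)
        merge_map, _ = tax.merge_by_correlation(m, groups, threshold=-1.0)
        assert len(set(merge_map.values())) == 1

    def test_cell_order_and_scale_invariance(self):
        C = np.array([[1.0, 0.55], [0.55, 1.0]])
        m, groups = correlated_groups_matrix(C, seed=2)
        map1, corr1 = tax.merge_by_correlation(m, groups)
        perm = np.random.default_rng(0).permutation(m.n_cells)
        m2 = m.subset_cells(perm)
        map2, corr2 = tax.merge_by_correlation(m2, groups[perm])
        assert map1 == map2
        m3 = m.copy()
        m3.X = m.X * 7.0
        map3, corr3 = tax.merge_by_correlation(m3, groups)
        assert map1 == map3
        np.testing.assert_allclose(corr1.values, corr3.values, atol=1e-12)

    def test_planted_class_partition_recovered(self, small_sim):
        _, matrix, truth = small_sim
        norm = tax.normalize_log(matrix)
        merge_map, corr = tax.merge_by_correlation(
            norm, truth.cells["subclass"].to_numpy(), threshold=0.49)
        sub2class = {s: c for s, c in
                     zip(truth.cells["subclass"], truth.cells["class"])}
        for s1 in merge_map:
            for s2 in merge_map:
                same_pred = merge_map[s1] == merge_map[s2]
                same_true = sub2class[s1] == sub2class[s2]
                assert same_pred == same_true


class TestDendrogram:
    def test_identical_centroids_merge_at_zero(self):
        X = np.tile(np.arange(10.0), (40, 1))
        m = make_matrix(np.zeros((40, 10), dtype=int))
        import scipy.sparse as sp
        m.X = sp.csr_matrix(X)
        groups = np.array(["a"] * 20 + ["b"] * 20)
        Z, names = tax.correlation_dendrogram(m, groups)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_close_pair_merges_first_and_heights_monotone(self):
        C = np.array([[1.0, 0.9, 0.1],
                      [0.9, 1.0, 0.1],
                      [0.1, 0.1, 1.0]])
        m, groups = correlated_groups_matrix(C, seed=4)
        Z, names = tax.correlation_dendrogram(m, groups)
        first = {names[int(Z[0, 0])], names[int(Z[0, 1])]}
        assert first == {"t0", "t1"}
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_newick_export(self):
        C = np.array([[1.0, 0.9, 0.1],
                      [0.9, 1.0, 0.1],
                      [0.1, 0.1, 1.0]])
        m, groups = correlated_groups_matrix(C, seed=4)
        Z, names = tax.correlation_dendrogram(m, groups)
        nwk = tax.dendrogram_to_newick(Z, names)
        assert nwk.endswith(";") and all(n in nwk for n in names)


# ----------------------------------------------------------------------
# functional panels
# ----------------------------------------------------------------------
class TestSubsetGenePanel:
    def test_prefix_match(self):
        m = make_matrix(np.ones((2, 3), dtype=int),
                        gene_names=["DRD1", "GABRA1", "ACTB"])
        sub = tax.subset_gene_panel(m, prefixes=("DRD", "GABR"))
        assert list(sub.var.index) == ["DRD1", "GABRA1"]

    def test_explicit_additions(self):
        m = make_matrix(np.ones((2, 4), dtype=int),
                        gene_names=["PEPL1", "POLR2M", "GCOM1", "ACTB"])
        sub = tax.subset_gene_panel(m, prefixes=("GRIN",),
                                    explicit=["PEPL1", "POLR2M", "GCOM1"])
        assert list(sub.var.index) == ["PEPL1", "POLR2M", "GCOM1"]

    def test_empty_match(self):
        m = make_matrix(np.ones((2, 2), dtype=int), gene_names=["A", "B"])
        sub = tax.subset_gene_panel(m, prefixes=("ZZZ",))
        assert sub.n_genes == 0
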
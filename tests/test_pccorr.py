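"""PCA loadings, loading processing, PC-corr scoring, combination, networks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import networkx as nx

from mechanomics import pccorr
from mechanomics.pccorr import (
    build_network,
    combine_pccorr,
    compute_pca,
    export_network,
    pccorr_matrix,
    percentile_cutoff,
    process_loadings,
    select_component,
    select_components_joint,
)


class TestComputePCA:
    def test_proportional_genes_hand_svd(self, make_ds):
        ds = make_ds([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]], groups=["a", "a", "b"])
        comps = compute_pca(ds, 1)
        np.testing.assert_allclose(
            comps[0].raw, np.array([1.0, 2.0]) / np.sqrt(5), atol=1e-12
        )
        np.testing.assert_allclose(
            comps[0].scores, [-np.sqrt(5), 0.0, np.sqrt(5)], atol=1e-12
        )

    def test_constant_gene_has_zero_loading(self, make_ds):
        ds = make_ds(
            [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [5.0, 5.0, 5.0]], groups=["a", "a", "b"]
        )
        comps = compute_pca(ds, 1)
        assert comps[0].raw[2] == pytest.approx(0.0, abs=1e-12)

    def test_single_gene_dataset(self, make_ds):
        ds = make_ds([[1.0, 3.0, 5.0]], groups=["a", "a", "b"])
        comps = compute_pca(ds, 1)
        assert abs(comps[0].raw[0]) == pytest.approx(1.0)
        np.testing.assert_allclose(comps[0].scores, [-2.0, 0.0, 2.0], atol=1e-12)

    def test_all_constant_matrix_rejected(self, make_ds):
        ds = make_ds([[1.0, 1.0], [2.0, 2.0]], groups=["a", "b"])
        with pytest.raises(ValueError, match="constant"):
            compute_pca(ds, 1)

    def test_raw_dataset_rejected(self, make_ds):
        ds = make_ds([[1.0, 2.0]], groups=["a", "b"], norm_state="raw")
        with pytest.raises(ValueError, match="normalized"):
            compute_pca(ds, 1)

    def test_sign_convention_largest_loading_positive(self, make_ds):
        rng = np.random.default_rng(3)
        ds = make_ds(rng.standard_normal((6, 5)))
        for comp in compute_pca(ds, 4):
            assert comp.raw[np.argmax(np.abs(comp.raw))] > 0

    def test_scores_reproduce_centered_data(self, make_ds):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((5, 4))
        ds = make_ds(x)
        comps = compute_pca(ds, 3)
        recon = sum(np.outer(c.raw, c.scores) for c in comps)
        np.testing.assert_allclose(recon, x - x.mean(axis=1, keepdims=True), atol=1e-10)


class TestSelectComponent:
    def test_fixed_index(self, make_ds):
        ds = make_ds(np.random.default_rng(0).standard_normal((5, 6)))
        comps = compute_pca(ds, 3)
        assert select_component(comps, ["a"] * 3 + ["b"] * 3, 1) == 1

    def test_auto_finds_dominant_mean_shift(self, make_ds):
        rng = np.random.default_rng(1)
        n = 10
        labels = np.array(["a"] * 5 + ["b"] * 5)
        shift = np.where(labels == "a", 4.0, -4.0)
        x = rng.standard_normal((8, n)) * 0.3 + shift  # all genes carry the shift
        ds = make_ds(x, groups=labels)
        comps = compute_pca(ds, 5)
        assert select_component(comps, labels, "auto") == 1

    def test_auto_skips_class_independent_top_variance(self, make_ds):
        # PC1 = a huge class-independent factor; the class shift sits on PC2
        rng = np.random.default_rng(2)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        factor = rng.standard_normal(12) * 50.0
        shift = np.where(labels == "a", 3.0, -3.0)
        x = np.vstack(
            [factor + rng.standard_normal(12) * 0.1 for _ in range(4)]
            + [shift + rng.standard_normal(12) * 0.1 for _ in range(4)]
        )
        ds = make_ds(x, groups=labels)
        comps = compute_pca(ds, 6)
        assert select_component(comps, labels, "auto") == 2

    def test_auto_requires_two_classes(self, make_ds):
        ds = make_ds(np.random.default_rng(0).standard_normal((4, 4)))
        comps = compute_pca(ds, 2)
        with pytest.raises(ValueError, match="two classes"):
            select_component(comps, ["a", "a", "a", "a"], "auto")


class TestProcessLoadings:
    def test_worked_vector(self):
        _, v = process_loadings(np.array([0.1, -0.2, 0.3]))
        np.testing.assert_allclose(v, [0.0, -0.56317079, 1.0], atol=1e-4)
        assert v[0] == 0.0 and v[2] == 1.0  # endpoints exact

    def test_equal_magnitudes_degenerate_case(self):
        _, v = process_loadings(np.array([0.4, -0.4]))
        np.testing.assert_array_equal(v, [1.0, -1.0])

    def test_largest_magnitude_maps_to_one(self):
        rng = np.random.default_rng(5)
        raw = rng.standard_normal(30)
        _, v = process_loadings(raw)
        assert np.max(np.abs(v)) == pytest.approx(1.0)
        # signs preserved wherever nonzero
        nz = v != 0
        np.testing.assert_array_equal(np.sign(v[nz]), np.sign(raw[nz]))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            process_loadings(np.zeros(3))


class TestPCCorrMatrix:
    def test_loading_bound_binds(self, make_ds):
        # construct data with a known correlation, then check the formula
        rng = np.random.default_rng(6)
        ds = make_ds(rng.standard_normal((3, 8)))
        v = np.array([0.9, 0.5, 0.0])
        res = pccorr_matrix(ds, v)
        c = np.corrcoef(ds.values)
        expected01 = np.sign(c[0, 1]) * min(0.9, 0.5, abs(c[0, 1]))
        assert res.pccorr[0, 1] == pytest.approx(expected01)
        # zero loading forces zero PC-corr
        assert res.pccorr[0, 2] == 0.0 and res.pccorr[1, 2] == 0.0
        assert np.all(np.diag(res.pccorr) == 0.0)

    def test_constant_row_pairs_zeroed(self, make_ds):
        ds = make_ds([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        res = pccorr_matrix(ds, np.array([1.0, 1.0]))
        assert res.pccorr[0, 1] == 0.0

    def test_brute_force_oracle_small(self, make_ds):
        """Direct per-pair formula evaluation matches the matrix path exactly."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            g = rng.integers(2, 7)
            ds = make_ds(rng.standard_normal((g, 6)))
            v = rng.uniform(-1, 1, g)
            res = pccorr_matrix(ds, v)
            for i in range(g):
                for j in range(g):
                    if i == j:
                        continue
                    c = np.corrcoef(ds.values[i], ds.values[j])[0, 1]
                    expected = np.sign(c) * min(abs(v[i]), abs(v[j]), abs(c))
                    assert res.pccorr[i, j] == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_invariants_fuzz(self, seed):
        rng = np.random.default_rng(seed)
        from tests.conftest import make_dataset

        g = int(rng.integers(2, 8))
        ds = make_dataset(rng.standard_normal((g, 5)))
        v = rng.uniform(-1, 1, g)
        res = pccorr_matrix(ds, v)
        absv = np.abs(v)
        bound = np.minimum.outer(absv, absv)
        off = ~np.eye(g, dtype=bool)
        assert np.all(np.abs(res.pccorr[off]) <= bound[off] + 1e-12)
        assert np.all(np.abs(res.pccorr) <= 1.0 + 1e-12)
        nz = (res.pccorr != 0) & off
        assert np.all(np.sign(res.pccorr[nz]) == np.sign(res.corr[nz]))
        np.testing.assert_allclose(res.pccorr, res.pccorr.T)

    def test_gene_scaling_leaves_signs(self, make_ds):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((4, 6))
        v = rng.uniform(-1, 1, 4)
        a = pccorr_matrix(make_ds(x), v)
        b = pccorr_matrix(make_ds(x * np.array([[2.0], [3.0], [0.5], [7.0]])), v)
        np.testing.assert_allclose(a.pccorr, b.pccorr, atol=1e-12)


class TestCombine:
    def _res(self, mat, name="d"):
        m = np.array(mat, dtype=float)
        g = m.shape[0]
        genes = [f"G{i}" for i in range(g)]
        np.fill_diagonal(m, 0)
        return pccorr.PCCorrResult(name, genes, np.ones_like(m), m)

    def test_mean_and_min(self):
        a = self._res([[0, 0.8], [0.8, 0]])
        b = self._res([[0, 0.6], [0.6, 0]], "e")
        assert combine_pccorr([a, b], "mean").comb[0, 1] == pytest.approx(0.7)
        assert combine_pccorr([a, b], "min").comb[0, 1] == pytest.approx(0.6)

    def test_sign_disagreement_masked(self):
        a = self._res([[0, 0.8], [0.8, 0]])
        b = self._res([[0, -0.6], [-0.6, 0]], "e")
        for method in ("mean", "min"):
            net = combine_pccorr([a, b], method)
            assert net.comb[0, 1] == 0.0
            assert net.sign_mask[0, 1] == 0

    def test_majority_sign_three_datasets(self):
        mats = [[[0, 0.9], [0.9, 0]], [[0, 0.3], [0.3, 0]], [[0, -0.6], [-0.6, 0]]]
        results = [self._res(m, f"d{i}") for i, m in enumerate(mats)]
        net = combine_pccorr(results, "min")
        assert net.comb[0, 1] == pytest.approx(0.3)
        assert net.sign_mask[0, 1] == 1

    def test_methods_agree_on_identical_magnitudes(self):
        rng = np.random.default_rng(9)
        m = rng.uniform(-1, 1, (4, 4))
        m = (m + m.T) / 2
        a, b = self._res(m), self._res(m, "e")
        np.testing.assert_allclose(
            combine_pccorr([a, b], "mean").comb, combine_pccorr([a, b], "min").comb
        )

    def test_mismatched_gene_lists_rejected(self):
        a = self._res(np.zeros((2, 2)))
        b = pccorr.PCCorrResult("e", ["X", "Y"], np.ones((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="gene lists differ"):
            combine_pccorr([a, b])


class TestBuildNetwork:
    def _combined(self, vals):
        genes = ["A", "B", "C"]
        comb = np.zeros((3, 3))
        for (i, j), v in vals.items():
            comb[i, j] = comb[j, i] = v
        return pccorr.CombinedNetwork(
            genes=genes, comb=comb, sign_mask=np.sign(comb).astype(int),
            method="mean", n_datasets=2,
        )

    def test_inclusive_threshold(self):
        c = self._combined({(0, 1): 0.8, (1, 2): 0.74, (0, 2): 0.2})
        net = build_network(c, 0.75)
        assert net.edges == [("A", "B", 0.8)]
        assert net.nodes == ["A", "B"]
        strict = build_network(c, 0.8, strict=True)
        assert strict.edges == []

    def test_cutoff_zero_keeps_all_nonzero(self):
        c = self._combined({(0, 1): 0.5, (1, 2): -0.1})
        net = build_network(c, 0.0)
        assert len(net.edges) == 2

    def test_cutoff_above_max_gives_empty(self):
        c = self._combined({(0, 1): 0.5})
        net = build_network(c, 0.9)
        assert net.edges == [] and net.nodes == []

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(10)
        m = rng.uniform(-1, 1, (8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        c = pccorr.CombinedNetwork(
            genes=[f"G{i}" for i in range(8)], comb=m,
            sign_mask=np.sign(m).astype(int), method="mean", n_datasets=2,
        )
        prev = None
        for cutoff in np.linspace(0, 1, 11):
            edges = {(a, b) for a, b, _ in build_network(c, cutoff).edges}
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_node_loading_is_mean_over_datasets(self):
        c = self._combined({(0, 1): 0.9})
        net = build_network(c, 0.5, node_loadings=[np.array([1.0, 0.5, 0.0]),
                                                   np.array([0.0, 0.5, 1.0])])
        assert net.node_loading == {"A": 0.5, "B": 0.5}


class TestExport:
    def test_counts_and_roundtrip(self, tmp_path):
        c = TestBuildNetwork()._combined({(0, 1): 0.8})
        net = build_network(c, 0.5, node_loadings=[np.ones(3)])
        files = export_network(net, tmp_path)
        edge_lines = (tmp_path / "network_edges.tsv").read_text().strip().split("\n")
        node_lines = (tmp_path / "network_nodes.tsv").read_text().strip().split("\n")
        assert len(edge_lines) == 2 and len(node_lines) == 3
        g = nx.read_graphml(tmp_path / "network.graphml")
        assert set(g.edges) == {("A", "B")}
        assert g.edges["A", "B"]["pccorr_comb"] == pytest.approx(0.8)

    def test_empty_network_writes_headers(self, tmp_path):
        c = TestBuildNetwork()._combined({(0, 1): 0.2})
        net = build_network(c, 0.9)
        export_network(net, tmp_path, formats=("edge-tsv",))
        assert (tmp_path / "network_edges.tsv").read_text() == "gene_i\tgene_j\tpccorr_comb\tsign\n"


def test_percentile_cutoff_matches_numpy():
    rng = np.random.default_rng(11)
    m = rng.uniform(-1, 1, (10, 10))
    m = (m + m.T) / 2
    c = pccorr.CombinedNetwork(
        genes=[f"G{i}" for i in range(10)], comb=m,
        sign_mask=np.sign(m).astype(int), method="mean", n_datasets=2,
    )
    iu, ju = np.triu_indices(10, 1)
    assert percentile_cutoff(c, 90) == pytest.approx(np.percentile(np.abs(m[iu, ju]), 90))


def test_joint_selection_recovers_shared_module(make_ds):
    """Two views sharing one correlated discriminative module: joint selection
    picks, in each view, the component carrying that module."""
    from mechanomics.datasets import normalize
    from mechanomics.simulate import SyntheticConfig, generate_study

    datasets, truth = generate_study(SyntheticConfig(G=120, m=5, d=3.0, rho=0.7, seed=12))
    views = []
    for ds in datasets:
        dsn = normalize(ds, "zscore")
        views.append((dsn, compute_pca(dsn, dsn.n_samples - 1)))
    ks = select_components_joint(views)
    assert len(ks) == 2
    for (dsn, comps), k in zip(views, ks):
        planted = [dsn.genes.index(g) for g in truth.planted_genes]
        chosen_mass = np.abs(comps[k - 1].processed[planted]).mean()
        assert chosen_mass > 0.5
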
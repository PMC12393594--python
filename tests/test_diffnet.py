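"""Differential networks, mutual-information estimation, DPI pruning and
hub analysis: exact oracles and structural invariants."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from stcelldyn import diffnet
from stcelldyn.diffnet import (aracne_network, delta_hub,
                               differential_network,
                               discretize_equal_frequency, dpi_prune,
                               mutual_information, region_specific_modules)


def mi_by_hand(x, y, n_bins):
    """Independent plug-in MI from the explicit contingency table."""
    def bins(v):
        order = np.argsort(v, kind="stable")
        b = np.empty(len(v), dtype=int)
        b[order] = (np.arange(len(v)) * n_bins) // len(v)
        return b
    bx, by = bins(np.asarray(x, float)), bins(np.asarray(y, float))
    n = len(x)
    mi = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            nij = np.sum((bx == i) & (by == j))
            if nij == 0:
                continue
            ni, nj = np.sum(bx == i), np.sum(by == j)
            mi += (nij / n) * math.log((nij / n) / ((ni / n) * (nj / n)))
    return mi


class TestMutualInformation:
    def test_three_gene_eight_sample_toy_matches_hand_values(self, rng):
        X = rng.normal(size=(8, 3))
        n_bins = int(np.ceil(np.sqrt(8)))
        for i, j in itertools.combinations(range(3), 2):
            got = mutual_information(X[:, i], X[:, j])
            assert got == pytest.approx(mi_by_hand(X[:, i], X[:, j], n_bins))

    def test_mi_nonnegative_and_self_maximal(self, rng):
        X = rng.normal(size=(40, 4))
        for i in range(4):
            self_mi = mutual_information(X[:, i], X[:, i])
            for j in range(4):
                mij = mutual_information(X[:, i], X[:, j])
                assert mij >= -1e-12
                assert self_mi >= mij - 1e-12

    def test_equal_frequency_bins_are_balanced(self, rng):
        x = rng.normal(size=100)
        b = discretize_equal_frequency(x, 10)
        assert (np.bincount(b) == 10).all()


class TestDPI:
    def test_noise_chain_indirect_edge_removed(self, rng):
        x = rng.normal(size=200)
        y = x + rng.normal(scale=0.3, size=200)
        z = y + rng.normal(scale=0.3, size=200)
        MI = np.zeros((3, 3))
        for i, j in itertools.combinations(range(3), 2):
            v = [x, y, z]
            MI[i, j] = MI[j, i] = mutual_information(v[i], v[j])
        pruned = dpi_prune(MI)
        assert pruned[0, 2] == 0.0  # X-Z is the weakest triangle edge
        assert pruned[0, 1] > 0 and pruned[1, 2] > 0

    def test_dpi_only_removes_edges(self, rng):
        MI = np.abs(rng.normal(size=(6, 6)))
        MI = (MI + MI.T) / 2
        np.fill_diagonal(MI, 0)
        pruned = dpi_prune(MI, tolerance=0.05)
        assert ((pruned > 0) <= (MI > 0)).all()
        assert ((pruned > 0).sum(1) <= (MI > 0).sum(1)).all()


class TestAracne:
    def test_independent_genes_have_sparse_network(self):
        rng = np.random.default_rng(0)
        M = pd.DataFrame(rng.normal(size=(50, 6)),
                         columns=[f"g{i}" for i in range(6)])
        net = aracne_network(M, n_perm=100, alpha=0.05, seed=0)
        degree = (net.to_numpy() > 0).sum(axis=1)
        assert degree.mean() <= 1.5

    def test_constant_gene_gets_zero_row(self, rng):
        M = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        M["a"] = 1.0
        net = aracne_network(M, n_perm=0)
        assert (net.loc["a"] == 0).all()

    def test_input_size_validation(self, rng):
        with pytest.raises(ValueError):
            aracne_network(pd.DataFrame(rng.normal(size=(3, 5))))
        with pytest.raises(ValueError):
            aracne_network(pd.DataFrame(rng.normal(size=(10, 2))))


class TestDifferentialNetwork:
    def _matrices(self, rng, n_regions=5, n_genes=12):
        regions = [f"R{i}" for i in range(n_regions)]
        genes = [f"g{i}" for i in range(n_genes)]
        A = pd.DataFrame(rng.normal(size=(n_regions, n_genes)),
                         index=regions, columns=genes)
        B = pd.DataFrame(rng.normal(size=(n_regions, n_genes)),
                         index=regions, columns=genes)
        return A, B, genes

    def test_identical_conditions_give_zero_deltas(self, rng):
        A, _, genes = self._matrices(rng)
        dn = differential_network(genes, A, A)
        assert np.allclose(dn.edges["delta"], 0.0)
        assert np.allclose(dn.edges["normalized_delta"], 0.0)

    def test_matches_brute_force_two_condition_differencing(self, rng):
        A, B, genes = self._matrices(rng)
        dn = differential_network(genes, A, B)
        for _, e in dn.edges.iterrows():
            r_sal = np.corrcoef(A.loc[e["region_a"]], A.loc[e["region_b"]])[0, 1]
            r_mor = np.corrcoef(B.loc[e["region_a"]], B.loc[e["region_b"]])[0, 1]
            assert e["delta"] == pytest.approx(r_mor - r_sal)

    def test_antisymmetric_under_condition_swap(self, rng):
        A, B, genes = self._matrices(rng)
        fwd = differential_network(genes, A, B)
        rev = differential_network(genes, B, A)
        f = fwd.edges.set_index(["region_a", "region_b"])["delta"]
        r = rev.edges.set_index(["region_a", "region_b"])["delta"]
        assert np.allclose(f, -r.loc[f.index])

    def test_planted_flip_has_unit_delta_and_ranks_first(self, rng):
        """One region pair's module correlation flips 0.8 -> -0.8; it must
        attain |normalized delta| = 1 and rank first."""
        genes = [f"g{i}" for i in range(20)]
        latent = rng.normal(size=20)
        regions = list("ABCDE")
        sal = {}
        mor = {}
        for i, r in enumerate(regions):
            noise = rng.normal(scale=0.6, size=20)
            sal[r] = latent + noise
            mor[r] = latent + noise  # same structure under MOR ...
        mor["B"] = -mor["B"]  # ... except region B flips against everything
        M_sal = pd.DataFrame(sal).T
        M_sal.columns = genes
        M_mor = pd.DataFrame(mor).T
        M_mor.columns = genes
        dn = differential_network(genes, M_sal, M_mor)
        top = dn.edges.iloc[0]
        assert "B" in (top["region_a"], top["region_b"])
        assert abs(top["normalized_delta"]) == pytest.approx(1.0)

    def test_max_edges_truncation(self, rng):
        A, B, genes = self._matrices(rng, n_regions=10)
        dn = differential_network(genes, A, B, max_edges=7)
        assert len(dn.edges) == 7

    def test_too_few_genes_rejected(self, rng):
        A, B, _ = self._matrices(rng)
        with pytest.raises(ValueError):
            differential_network(["g0"], A, B)


class TestDeltaHub:
    def _net(self, genes, edges):
        net = pd.DataFrame(0.0, index=genes, columns=genes)
        for a, b, w in edges:
            net.loc[a, b] = net.loc[b, a] = w
        return net

    def test_identical_networks_all_zero_with_tie_rule(self):
        genes = list("abcd")
        net = self._net(genes, [("a", "b", 1.0), ("c", "d", 0.5)])
        res = delta_hub(net, net, top_k=2)
        assert (res.table["delta_hub"] == 0).all()
        # ties: higher MOR degree first, then lexicographic
        assert res.top_hubs == ["a", "b"]

    def test_planted_degree_gain_selected(self):
        genes = [f"g{i}" for i in range(8)]
        sal = self._net(genes, [("g0", "g1", 0.5)])
        mor = self._net(genes, [("g0", "g1", 0.5)]
                        + [("g7", g, 0.9) for g in genes[1:6]])
        res = delta_hub(sal, mor, top_k=1)
        assert res.top_hubs == ["g7"]
        assert res.table.set_index("gene").loc["g7", "delta_hub"] == 5

    def test_subnetwork_truncated_to_max_nodes_by_weight(self, rng):
        genes = [f"g{i:02d}" for i in range(40)]
        hub = "g00"
        weights = rng.uniform(0.1, 1.0, 39)
        mor = self._net(genes, [(hub, g, w) for g, w in
                                zip(genes[1:], weights)])
        sal = self._net(genes, [])
        res = delta_hub(sal, mor, top_k=1, max_nodes=25)
        assert len(res.subnetwork_nodes) == 25
        kept_w = sorted(weights, reverse=True)[:24]
        got_w = [mor.loc[hub, g] for g in res.subnetwork_nodes[1:]]
        assert sorted(got_w, reverse=True) == pytest.approx(kept_w)


class TestRegionSpecificModules:
    def test_constant_eigengene_never_flagged(self):
        E = pd.DataFrame({"blue": np.ones(6)},
                         index=[f"R{i}" for i in range(6)])
        out = region_specific_modules(E)
        assert not out["region_specific"].any()

    def test_planted_outlier_region_flagged_single(self, rng):
        v = rng.normal(scale=0.1, size=8)
        v[3] = 3.0
        E = pd.DataFrame({"blue": v}, index=[f"R{i}" for i in range(8)])
        out = region_specific_modules(E)
        hit = out[out["region_specific"]]
        assert list(hit["region"]) == ["R3"]
        assert hit["single_region"].all()

    def test_z_matches_hand_computation(self, rng):
        v = rng.normal(size=8)
        E = pd.DataFrame({"m": v}, index=[f"R{i}" for i in range(8)])
        out = region_specific_modules(E).set_index("region")
        expect = (v - v.mean()) / v.std()
        for i in range(8):
            assert out.loc[f"R{i}", "z"] == pytest.approx(expect[i])

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            region_specific_modules(pd.DataFrame({"m": [1.0, 2.0]}))
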
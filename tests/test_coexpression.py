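"""Region matrices, inter-regional networks, bicor/TOM oracles, module
detection recovery, module-trait correlation and Fisher enrichment."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from stcelldyn import coexpression as cx


class TestRegionMeanMatrix:
    def _cells(self, regions):
        df = pd.DataFrame({"region_d7": regions})
        df["sample"] = "AA_SAL"
        return df

    def test_three_region_toy_equals_direct_means(self, rng):
        X = rng.normal(size=(30, 4))
        regions = np.repeat(["A", "B", "C"], 10)
        M, counts = cx.region_mean_matrix(X, self._cells(regions),
                                          min_cells=1, seed=0,
                                          gene_names=list("wxyz"))
        for r in "ABC":
            assert np.allclose(M.loc[r], X[regions == r].mean(axis=0))
        assert (counts == 10).all()

    def test_single_cell_row_equals_profile(self, rng):
        X = rng.normal(size=(3, 4))
        M, _ = cx.region_mean_matrix(X, self._cells(["A", "B", "C"]),
                                     min_cells=1, seed=0)
        assert np.allclose(M.loc["B"], X[1])

    def test_subsampling_is_seeded(self, rng):
        X = rng.normal(size=(200, 5))
        cells = self._cells(np.repeat(["A", "B"], 100))
        M1, _ = cx.region_mean_matrix(X, cells, sample_n=50, min_cells=1, seed=3)
        M2, _ = cx.region_mean_matrix(X, cells, sample_n=50, min_cells=1, seed=3)
        pd.testing.assert_frame_equal(M1, M2)

    def test_min_cells_filter(self, rng):
        X = rng.normal(size=(12, 3))
        M, _ = cx.region_mean_matrix(
            X, self._cells(["A"] * 10 + ["B"] * 2), min_cells=5, seed=0)
        assert list(M.index) == ["A"]


class TestInterregionNetwork:
    def test_duplicated_regions_form_unit_edge(self, rng):
        prof = rng.normal(size=20)
        M = pd.DataFrame([prof, prof, rng.normal(size=20)],
                         index=["A", "A2", "B"])
        edges, cent, R = cx.interregion_network(M, r_min=0.95)
        assert {("A", "A2")} == set(zip(edges["region_a"], edges["region_b"]))
        assert edges["r"].iloc[0] == pytest.approx(1.0)

    def test_matrix_matches_brute_force_pearson(self, rng):
        M = pd.DataFrame(rng.normal(size=(4, 30)), index=list("ABCD"))
        _, cent, R = cx.interregion_network(M, r_min=0.5)
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                expect = np.corrcoef(M.loc[a], M.loc[b])[0, 1]
                assert R.loc[a, b] == pytest.approx(expect)
        assert ((0 <= cent) & (cent <= 1)).all()

    def test_independent_profiles_have_no_edges(self):
        for s in range(3):
            rng = np.random.default_rng(s)
            M = pd.DataFrame(rng.normal(size=(6, 1000)))
            edges, _, _ = cx.interregion_network(M, r_min=0.95)
            assert len(edges) == 0


class TestBicor:
    def test_matches_pearson_on_gaussian_data(self, rng):
        X = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=500)
        b = cx.bicor(X)[0, 1]
        p = np.corrcoef(X.T)[0, 1]
        assert abs(b - p) < 0.05

    def test_robust_to_single_outlier(self, rng):
        x = rng.normal(size=100)
        y = x + rng.normal(scale=0.1, size=100)
        y[0] = 1000.0
        b = cx.bicor(np.column_stack([x, y]))[0, 1]
        assert b > 0.9  # Pearson would collapse toward 0

    def test_constant_column_falls_back_without_error(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        B = cx.bicor(X)
        assert np.isfinite(B[1, 1]) and B[1, 1] == pytest.approx(1.0)


class TestTom:
    def test_five_gene_toy_matches_hand_formula(self, rng):
        A = np.abs(rng.uniform(0.1, 0.9, size=(5, 5)))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        T = cx.tom_similarity(A)
        k = A.sum(axis=1)
        for i in range(5):
            for j in range(5):
                if i == j:
                    assert T[i, j] == 1.0
                    continue
                l_ij = sum(A[i, u] * A[u, j] for u in range(5)
                           if u not in (i, j))
                expect = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
                assert T[i, j] == pytest.approx(expect)

    def test_tom_symmetric_unit_diagonal_bounded(self, rng):
        A = np.abs(cx.bicor(rng.normal(size=(30, 12)))) ** 6
        T = cx.tom_similarity(A)
        assert np.allclose(T, T.T)
        assert np.allclose(np.diag(T), 1.0)
        assert T.min() >= 0 and T.max() <= 1 + 1e-12


class TestSoftPower:
    def test_heterogeneous_modular_structure_passes_at_low_power(self, rng):
        # modules of unequal size and membership strength produce the
        # heavy-tailed connectivity the scale-free criterion looks for
        n = 50
        blocks = []
        for gpm in (40, 20, 10, 5):
            latent = rng.normal(size=n)
            noise = rng.uniform(0.2, 2.5, size=gpm)
            blocks.append(np.outer(latent, np.ones(gpm))
                          + rng.normal(size=(n, gpm)) * noise)
        blocks.append(rng.normal(size=(n, 25)))
        M = pd.DataFrame(np.hstack(blocks))
        p, fit = cx.pick_soft_power(M)
        assert p <= 8
        assert fit.loc[fit["power"] == p, "signed_r2"].iloc[0] > 0.8

    def test_pure_noise_falls_back_to_default_with_warning(self, rng):
        M = pd.DataFrame(rng.normal(size=(30, 60)))
        with pytest.warns(UserWarning):
            p, _ = cx.pick_soft_power(M, r2_min=0.999)
        assert p == 8

    def test_power_one_adjacency_is_abs_bicor(self, rng):
        X = rng.normal(size=(25, 6))
        assert np.allclose(np.abs(cx.bicor(X)) ** 1, np.abs(cx.bicor(X)))


class TestDetectModules:
    def _modular_matrix(self, rng, n=40, gpm=30, k=4, noise=0.5):
        blocks, truth = [], []
        for m in range(k):
            latent = rng.normal(size=n)
            sign = rng.choice([-1, 1], size=gpm)
            blocks.append(np.outer(latent, sign)
                          + rng.normal(scale=noise, size=(n, gpm)))
            truth.extend([m] * gpm)
        M = pd.DataFrame(np.hstack(blocks),
                         columns=[f"g{i}" for i in range(k * gpm)])
        return M, np.array(truth)

    def test_recovers_planted_orthogonal_modules(self, rng):
        M, truth = self._modular_matrix(rng)
        mods = cx.detect_modules(M)
        pred = mods.assignment.to_numpy()
        assert adjusted_rand_score(truth, pred) >= 0.8

    def test_merge_cut_zero_never_merges(self, rng):
        M, _ = self._modular_matrix(rng)
        mods = cx.detect_modules(M, merge_cut=0.0)
        assert mods.merge_history == []

    def test_too_few_genes_gives_grey(self, rng):
        M = pd.DataFrame(rng.normal(size=(10, 5)),
                         columns=list("abcde"))
        with pytest.warns(UserWarning):
            mods = cx.detect_modules(M, min_size=20)
        assert (mods.assignment == "grey").all()

    def test_eigengene_is_dominant_direction(self, rng):
        M, truth = self._modular_matrix(rng, k=2)
        mods = cx.detect_modules(M)
        for m in mods.modules:
            genes = mods.genes_of(m)
            sub = M[genes].to_numpy()
            Z = (sub - sub.mean(0)) / sub.std(0)
            e = mods.eigengenes[m].to_numpy()
            # unit-norm scores; first-PC variance >= any single gene share
            var_e = (Z.T @ e / np.linalg.norm(Z.T @ e)) @ (Z.T @ e)
            per_gene = (Z ** 2).sum(axis=0)
            assert np.linalg.norm(e) == pytest.approx(1.0)
            assert (Z.T @ e @ (Z.T @ e)) >= per_gene.max() - 1e-6

    def test_module_recovery_on_default_fixture(self, processed):
        ds, X, gene_names, cells, truth, report, ckeep = processed
        rows = {}
        for grp in ("AA_SAL", "AA_MOR", "GG_SAL", "GG_MOR"):
            M, _ = cx.region_mean_matrix(X, cells, group=grp, min_cells=100,
                                         seed=0, gene_names=gene_names)
            for r in M.index:
                rows[f"{r}_{grp}"] = M.loc[r]
        pooled = pd.DataFrame(rows).T
        mods = cx.detect_modules(pooled)
        mt = ds.truth.module_truth
        genes = [g for g in mt if g in mods.assignment.index]
        ari = adjusted_rand_score([mt[g] for g in genes],
                                  mods.assignment[genes])
        assert ari >= 0.8


class TestModuleTrait:
    def _mods(self, rng, n=12):
        eig = pd.DataFrame({"blue": rng.normal(size=n)})
        eig["blue"] /= np.linalg.norm(eig["blue"])
        return cx.ModuleSet(assignment=pd.Series({"a": "blue"}),
                            eigengenes=eig)

    def test_trait_equal_to_eigengene_has_r_one(self, rng):
        mods = self._mods(rng)
        traits = pd.DataFrame({"t": mods.eigengenes["blue"]})
        r, p = cx.module_trait(mods, traits)
        assert r.loc["blue", "t"] == pytest.approx(1.0)
        assert p.loc["blue", "t"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_trait_is_nan(self, rng):
        mods = self._mods(rng)
        r, p = cx.module_trait(mods, pd.DataFrame({"t": np.ones(12)}))
        assert np.isnan(r.loc["blue", "t"])

    def test_six_sample_hand_pearson(self, rng):
        mods = self._mods(rng, n=6)
        y = rng.integers(0, 2, 6).astype(float)
        r, _ = cx.module_trait(mods, pd.DataFrame({"t": y}))
        expect = np.corrcoef(mods.eigengenes["blue"], y)[0, 1]
        assert r.loc["blue", "t"] == pytest.approx(expect)


class TestFisherEnrichment:
    def _modules(self):
        assign = pd.Series({f"g{i}": ("blue" if i < 10 else "brown")
                            for i in range(20)})
        return cx.ModuleSet(assignment=assign, eigengenes=pd.DataFrame())

    def test_containment_matches_hypergeometric_enumeration(self):
        mods = self._modules()
        universe = [f"g{i}" for i in range(20)]
        sets = {"eff": [f"g{i}" for i in range(6)]}  # inside blue
        E = cx.fisher_module_enrichment(mods, sets, universe)
        # exact tail: P(hits >= 6) drawing 10 (blue) of 20 with 6 marked
        denom = math.comb(20, 6)
        p = sum(math.comb(10, k) * math.comb(10, 6 - k) for k in (6,)) / denom
        assert E.loc["blue", "eff"] == pytest.approx(
            min(-np.log10(p), 10.0), abs=1e-9)

    def test_cap_applied(self, rng):
        assign = pd.Series({f"g{i}": "blue" if i < 300 else "brown"
                            for i in range(600)})
        mods = cx.ModuleSet(assignment=assign, eigengenes=pd.DataFrame())
        sets = {"eff": [f"g{i}" for i in range(300)]}
        E = cx.fisher_module_enrichment(mods, sets,
                                        [f"g{i}" for i in range(600)])
        assert E.loc["blue", "eff"] == 10.0

    def test_empty_set_scores_zero(self):
        mods = self._modules()
        E = cx.fisher_module_enrichment(mods, {"eff": []},
                                        [f"g{i}" for i in range(20)])
        assert (E["eff"] == 0).all()

    def test_normalized_values_bounded(self, rng):
        mods = self._modules()
        sets = {"eff": [f"g{i}" for i in rng.integers(0, 20, 8)]}
        E = cx.fisher_module_enrichment(mods, sets,
                                        [f"g{i}" for i in range(20)])
        assert E["eff_norm"].between(0, 1).all()


class TestPrioritize:
    def _matrix(self):
        return pd.DataFrame(
            {"OUD": [1.0, 5.0, 2.0, 0.0, 3.0],
             "DEG_TREAT_AA": [10.0, 2.0, 2.0, 1.0, 0.0],
             "DEG_TREAT_GG": [0.0, 2.0, 1.0, 6.0, 0.0]},
            index=["blue", "brown", "green", "red", "yellow"])

    def test_extreme_genotype_difference_ranks_first(self):
        out = cx.prioritize_modules(self._matrix())
        assert out["by_genotype_difference"][0] == "blue"  # |10-0| = 10

    def test_all_ties_resolve_by_label_order(self):
        E = pd.DataFrame({"DEG_TREAT_AA": [1.0, 1.0], "DEG_TREAT_GG":
                          [1.0, 1.0]}, index=["zed", "abc"])
        out = cx.prioritize_modules(E)
        assert out["by_genotype_difference"] == ["abc", "zed"]

    def test_union_is_deduplicated_and_stable(self):
        out = cx.prioritize_modules(self._matrix(), top_k=2)
        u = out["union_top"]
        assert len(u) == len(set(u))
        assert u[0] == "blue" and u[1] == "red"
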
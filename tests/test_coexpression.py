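"""Soft adjacency, TOM, module cutting/merging, eigengenes, module-trait correlation."""

import numpy as np
import pandas as pd
import pytest

from triomics import (
    NetworkConfig,
    TriomicsError,
    cut_modules,
    module_eigengene,
    module_trait_correlation,
    soft_adjacency,
    tom_similarity,
)
from triomics.coexpression import GREY
from triomics.simulate import simulate_module_expression


def _expr(vals, prefix="g"):
    vals = np.asarray(vals, dtype=float)
    return pd.DataFrame(vals, index=[f"{prefix}{i}" for i in range(vals.shape[0])],
                        columns=[f"s{j}" for j in range(vals.shape[1])])


class TestAdjacency:
    def test_perfect_correlation_is_one_for_any_beta(self, rng):
        x = rng.normal(size=8)
        e = _expr([x, 2 * x + 3])
        for beta in (1, 6, 18):
            a = soft_adjacency(e, NetworkConfig(beta=beta))
            assert a.iloc[0, 1] == pytest.approx(1.0)

    def test_arithmetic_at_beta_two(self):
        # construct two vectors with correlation exactly 0.5
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, -1.0, 1.0])
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.5)
        a = soft_adjacency(_expr([x, y]), NetworkConfig(beta=2))
        assert a.iloc[0, 1] == pytest.approx(0.25, abs=1e-12)

    def test_matches_elementwise_oracle(self, rng):
        e = _expr(rng.normal(size=(20, 10)))
        beta = 7
        a = soft_adjacency(e, NetworkConfig(beta=beta)).to_numpy()
        cor = np.corrcoef(e.to_numpy())
        oracle = np.abs(cor) ** beta
        np.fill_diagonal(oracle, 1.0)
        np.testing.assert_allclose(a, oracle, atol=1e-12)

    def test_signed_variant(self, rng):
        e = _expr(rng.normal(size=(10, 8)))
        a = soft_adjacency(e, NetworkConfig(beta=3, network_type="signed")).to_numpy()
        cor = np.corrcoef(e.to_numpy())
        oracle = ((1 + cor) / 2) ** 3
        np.fill_diagonal(oracle, 1.0)
        np.testing.assert_allclose(a, oracle, atol=1e-12)


def _tom_bruteforce(A):
    n = A.shape[0]
    k = A.sum(axis=1) - np.diag(A)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


class TestTOM:
    def test_identity_adjacency_gives_zero_overlap(self):
        T = tom_similarity(np.eye(5))
        assert np.allclose(T - np.eye(5), 0.0)

    def test_complete_graph_gives_full_overlap(self):
        T = tom_similarity(np.ones((6, 6)))
        np.testing.assert_allclose(T, 1.0)

    @pytest.mark.parametrize("n", [6, 12, 30])
    def test_matches_triple_loop_oracle(self, rng, n):
        C = rng.uniform(0, 1, size=(n, n))
        A = (C + C.T) / 2
        np.fill_diagonal(A, 1.0)
        T = tom_similarity(A)
        np.testing.assert_allclose(T, _tom_bruteforce(A), atol=1e-12)
        assert (T >= 0).all() and (T <= 1).all()
        np.testing.assert_allclose(T, T.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(T), 1.0)

    def test_two_feature_system_equals_adjacency(self):
        A = np.array([[1.0, 0.37], [0.37, 1.0]])
        np.testing.assert_allclose(tom_similarity(A), A, atol=1e-12)

    def test_asymmetry_rejected(self):
        A = np.eye(3)
        A[0, 1] = 0.5
        with pytest.raises(TriomicsError, match="symmetric"):
            tom_similarity(A)


class TestModules:
    def test_planted_blocks_recovered(self):
        expr, _ = simulate_module_expression(
            [(40, 0.9, 0.0), (40, 0.9, 0.0)], seed=3
        )
        cfg = NetworkConfig(beta=6, min_module_size=30)
        tom = tom_similarity(soft_adjacency(expr, cfg))
        res = cut_modules(1.0 - tom, cfg, expr=expr)
        non_grey = res.labels[res.labels != GREY]
        assert non_grey.nunique() == 2
        # each recovered module is one planted block
        for mod in non_grey.unique():
            members = non_grey.index[non_grey == mod]
            blocks = {m.split("_")[0] for m in members}
            assert len(blocks) == 1 and len(members) == 40

    def test_min_module_size_above_feature_count_makes_all_grey(self, rng):
        expr = _expr(rng.normal(size=(10, 8)))
        cfg = NetworkConfig(beta=2, min_module_size=50)
        tom = tom_similarity(soft_adjacency(expr, cfg))
        with pytest.warns(UserWarning):
            res = cut_modules(1.0 - tom, cfg)
        assert (res.labels == GREY).all()

    def test_merge_height_zero_disables_merging(self):
        expr, _ = simulate_module_expression([(35, 0.9, 0.0), (35, 0.9, 0.0)], seed=4)
        cfg0 = NetworkConfig(beta=6, min_module_size=30, merge_cut_height=0.0)
        tom = tom_similarity(soft_adjacency(expr, cfg0))
        res0 = cut_modules(1.0 - tom, cfg0, expr=expr)
        assert res0.labels[res0.labels != GREY].nunique() == 2

    def test_merging_monotone_in_cut_height(self):
        expr, _ = simulate_module_expression(
            [(35, 0.85, 0.0), (35, 0.85, 0.0), (35, 0.85, 0.0)], seed=5
        )
        counts = []
        for h in (0.0, 0.25, 0.7, 1.0 - 1e-9):
            cfg = NetworkConfig(beta=6, min_module_size=30, merge_cut_height=h)
            tom = tom_similarity(soft_adjacency(expr, cfg))
            res = cut_modules(1.0 - tom, cfg, expr=expr)
            counts.append(res.labels[res.labels != GREY].nunique())
        assert counts == sorted(counts, reverse=True)

    def test_labels_invariant_under_permutation(self, rng):
        expr, _ = simulate_module_expression([(35, 0.9, 0.0), (35, 0.9, 0.0)], seed=6)
        perm = rng.permutation(len(expr))
        cfg = NetworkConfig(beta=6, min_module_size=30)
        res1 = cut_modules(1.0 - tom_similarity(soft_adjacency(expr, cfg)), cfg, expr=expr)
        exprp = expr.iloc[perm]
        res2 = cut_modules(1.0 - tom_similarity(soft_adjacency(exprp, cfg)), cfg, expr=exprp)
        # same partition up to label names
        for mod in res1.labels.unique():
            members = set(res1.labels.index[res1.labels == mod])
            mapped = {res2.labels[m] for m in members}
            assert len(mapped) == 1


class TestEigengene:
    def test_identical_members_give_profile_direction(self, rng):
        x = rng.normal(size=10)
        expr = _expr([x, x, x, x])
        labels = pd.Series(["blue"] * 4, index=expr.index)
        eig = module_eigengene(expr, labels)
        xs = (x - x.mean()) / x.std(ddof=1)
        v = eig.loc["blue"].to_numpy()
        assert abs(np.corrcoef(v, xs)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(v, x)[0, 1] > 0   # positive orientation
        assert np.linalg.norm(v) == pytest.approx(1.0)

    def test_matches_svd_oracle_up_to_sign(self, rng):
        expr = _expr(rng.normal(size=(12, 9)))
        labels = pd.Series(["red"] * 12, index=expr.index)
        eig = module_eigengene(expr, labels).loc["red"].to_numpy()
        X = expr.to_numpy()
        Xs = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
        _, _, Vt = np.linalg.svd(Xs, full_matrices=False)
        assert np.allclose(eig, Vt[0], atol=1e-8) or np.allclose(eig, -Vt[0], atol=1e-8)

    def test_explains_most_variance(self, rng):
        expr = _expr(rng.normal(size=(8, 10)))
        labels = pd.Series(["m"] * 8, index=expr.index)
        eig = module_eigengene(expr, labels).loc["m"].to_numpy()
        X = expr.to_numpy()
        Xs = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
        var_eig = ((Xs @ eig) ** 2).sum()
        for row in Xs:
            u = row / np.linalg.norm(row)
            assert var_eig >= ((Xs @ u) ** 2).sum() - 1e-9


class TestModuleTrait:
    def test_eigengene_equal_to_trait_is_significant(self):
        trait = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        e = (trait - trait.mean()) / np.linalg.norm(trait - trait.mean())
        eig = pd.DataFrame([e], index=["blue"], columns=[f"s{i}" for i in range(12)])
        res = module_trait_correlation(eig, trait)
        assert res["r"].iloc[0] == pytest.approx(1.0)
        assert bool(res["significant"].iloc[0])

    def test_orthogonal_eigengene_not_significant(self):
        trait = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        e = np.array([1, -1, 1, -1, 1, -1, 1, -1], dtype=float)
        eig = pd.DataFrame([e / np.linalg.norm(e)], index=["m"],
                           columns=[f"s{i}" for i in range(8)])
        res = module_trait_correlation(eig, trait)
        assert res["r"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert not bool(res["significant"].iloc[0])

    def test_hybrid_suppressed_module_yields_negative_correlation(self):
        """A module shifted down by 2 SD in hybrids correlates negatively with
        the parents=0/hybrids=1 trait at |r| > 0.6, P < 0.05."""
        expr, trait = simulate_module_expression([(40, 0.9, 2.0)], seed=8)
        cfg = NetworkConfig(beta=6, min_module_size=30)
        tom = tom_similarity(soft_adjacency(expr, cfg))
        res = cut_modules(1.0 - tom, cfg, expr=expr)
        mt = module_trait_correlation(res.eigengenes, trait)
        assert len(mt) == 1
        assert mt["r"].iloc[0] < -0.6
        assert mt["p"].iloc[0] < 0.05
        assert bool(mt["significant"].iloc[0])
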
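"""Size factors, NB Wald test, BH adjustment, Welch t, PLS-DA VIP, two-way ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triomics import (
    OmicsMatrix,
    ThresholdConfig,
    TriomicsError,
    bh_adjust,
    call_dams,
    nb_test,
    plsda_vip,
    size_factors,
    two_way_anova,
    vip_table,
    welch_t_test,
)


def _counts(vals, prefix="s"):
    vals = np.asarray(vals)
    return OmicsMatrix(
        pd.DataFrame(vals, index=[f"g{i}" for i in range(vals.shape[0])],
                     columns=[f"{prefix}{j}" for j in range(vals.shape[1])]),
        "counts",
    )


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        m = _counts(np.tile([[10], [20], [30]], (1, 4)))
        np.testing.assert_allclose(size_factors(m), 1.0, atol=1e-12)

    def test_doubled_sample_scale_equivariance(self):
        base = np.array([[10, 10, 20], [30, 30, 60], [5, 5, 10]])
        sf = size_factors(_counts(base))
        assert sf[2] / sf[0] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_matches_median_of_ratios_oracle(self, rng):
        vals = rng.negative_binomial(20, 0.2, size=(100, 5)) + 1
        sf = size_factors(_counts(vals))
        geo = np.exp(np.mean(np.log(vals), axis=1))
        raw = np.median(vals / geo[:, None], axis=0)
        oracle = raw / np.exp(np.mean(np.log(raw)))
        np.testing.assert_allclose(sf, oracle, rtol=1e-12)


class TestNBTest:
    def test_identical_groups_are_null(self, rng):
        half = rng.negative_binomial(20, 0.2, size=(50, 3))
        m = _counts(np.hstack([half, half]))
        res = nb_test(m, [f"s{j}" for j in range(3)], [f"s{j}" for j in range(3, 6)])
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)
        assert (res["p"] > 0.99).all()

    def test_group_swap_symmetry(self, rng):
        vals = rng.negative_binomial(10, 0.1, size=(60, 6))
        m = _counts(vals)
        a, b = [f"s{j}" for j in range(3)], [f"s{j}" for j in range(3, 6)]
        r1 = nb_test(m, a, b)
        r2 = nb_test(m, b, a)
        np.testing.assert_allclose(r1["log2fc"], -r2["log2fc"], atol=1e-12)
        np.testing.assert_allclose(r1["p"], r2["p"], atol=1e-12)

    def test_overlapping_groups_rejected(self, rng):
        m = _counts(rng.integers(0, 10, size=(5, 4)))
        with pytest.raises(TriomicsError, match="overlap"):
            nb_test(m, ["s0", "s1"], ["s1", "s2"])

    def test_all_zero_gene_is_flat_null(self, rng):
        vals = rng.integers(5, 50, size=(10, 6))
        vals[3] = 0
        res = nb_test(_counts(vals), [f"s{j}" for j in range(3)],
                      [f"s{j}" for j in range(3, 6)])
        assert res.loc[3, "log2fc"] == 0.0
        assert res.loc[3, "p"] == 1.0

    def test_null_type_one_error_calibrated(self):
        """10,000 null NB genes at 3v3: p<0.05 fraction within [0.035, 0.065]."""
        rng = np.random.default_rng(11)
        r = 1 / 0.05
        vals = rng.negative_binomial(r, r / (r + 100.0), size=(10_000, 6))
        res = nb_test(_counts(vals), [f"s{j}" for j in range(3)],
                      [f"s{j}" for j in range(3, 6)])
        frac = float((res["p"] < 0.05).mean())
        assert 0.035 <= frac <= 0.065

    def test_power_on_planted_fourfold_change(self):
        """1,000 genes with a true 4-fold change inside a null background are
        called at FC > 1.5, FDR < 0.3 at >= 80% power."""
        rng = np.random.default_rng(5)
        r = 1 / 0.05
        bgA = rng.negative_binomial(r, r / (r + 200.0), size=(4000, 3))
        bgB = rng.negative_binomial(r, r / (r + 200.0), size=(4000, 3))
        A = rng.negative_binomial(r, r / (r + 200.0), size=(1000, 3))
        B = rng.negative_binomial(r, r / (r + 800.0), size=(1000, 3))
        m = _counts(np.hstack([np.vstack([bgA, A]), np.vstack([bgB, B])]))
        res = nb_test(m, [f"s{j}" for j in range(3)], [f"s{j}" for j in range(3, 6)])
        assert (res["call"].iloc[4000:] == "up").mean() >= 0.8


class TestBH:
    def test_single_p(self):
        np.testing.assert_allclose(bh_adjust([0.04]), [0.04])

    def test_hand_stepup_enumeration(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_q_at_least_p_and_rank_monotone(self, rng):
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_matches_statsmodels_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 60))
            np.testing.assert_allclose(
                bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    def test_discoveries_monotone_in_cut(self, rng):
        q = bh_adjust(rng.uniform(size=500) ** 2)
        counts = [(q < c).sum() for c in (0.01, 0.05, 0.1, 0.3)]
        assert counts == sorted(counts)

    def test_nan_propagates(self):
        with pytest.warns(UserWarning):
            q = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])


class TestWelch:
    def test_identical_vectors(self):
        t, df, p = welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_clear_separation(self):
        # a +10 shift at n=3 is about as significant as Welch df allows
        _, _, p = welch_t_test([1, 2, 3], [11.01, 12.0, 12.99])
        assert p < 1e-3

    def test_matches_textbook_formula(self, rng):
        x, y = rng.normal(size=8), rng.normal(1.0, 2.0, size=5)
        t, df, p = welch_t_test(x, y)
        sx2, sy2 = x.var(ddof=1) / 8, y.var(ddof=1) / 5
        t0 = (x.mean() - y.mean()) / np.sqrt(sx2 + sy2)
        df0 = (sx2 + sy2) ** 2 / (sx2**2 / 7 + sy2**2 / 4)
        assert t == pytest.approx(t0, abs=1e-10)
        assert df == pytest.approx(df0, abs=1e-10)
        assert p == pytest.approx(2 * stats.t.sf(abs(t0), df0), abs=1e-10)

    def test_zero_variance_conventions(self):
        assert welch_t_test([2, 2, 2], [2, 2, 2])[2] == 1.0
        with pytest.warns(UserWarning):
            assert welch_t_test([2, 2, 2], [3, 3, 3])[2] == 0.0


class TestVIP:
    def test_single_feature_is_exactly_one(self, rng):
        X = rng.normal(size=(10, 1))
        y = [0] * 5 + [1] * 5
        np.testing.assert_allclose(plsda_vip(X, y, 1), [1.0], atol=1e-12)

    def test_duplicate_features_get_equal_vip(self, rng):
        x = rng.normal(size=12)
        X = np.column_stack([x, x, rng.normal(size=12)])
        y = [0] * 6 + [1] * 6
        v = plsda_vip(X, y, 2)
        assert v[0] == pytest.approx(v[1], abs=1e-10)

    def test_mean_squared_vip_is_one(self, rng):
        for _ in range(5):
            X = rng.normal(size=(14, 9))
            y = [0] * 7 + [1] * 7
            v = plsda_vip(X, y, 3)
            assert np.mean(v**2) == pytest.approx(1.0, abs=1e-8)

    def test_single_component_matrix_algebra_oracle(self, rng):
        """VIP at 1 component equals sqrt(p)|w|/||w|| with w = Xs'y, coded directly."""
        X = rng.normal(size=(12, 8))
        y = np.array([0] * 6 + [1] * 6)
        v = plsda_vip(X, y, 1)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        w = Xs.T @ (y - y.mean())
        oracle = np.sqrt(8) * np.abs(w) / np.linalg.norm(w)
        np.testing.assert_allclose(v, oracle, atol=1e-10)

    def test_constant_feature_raises_with_name(self, rng):
        X = rng.normal(size=(8, 3))
        X[:, 1] = 5.0
        with pytest.raises(TriomicsError, match="m2"):
            plsda_vip(X, [0] * 4 + [1] * 4, 1, feature_ids=["m1", "m2", "m3"])


class TestCallDams:
    @pytest.mark.parametrize(
        "vip, fdr, kept",
        [(1.0, 0.01, False), (2.0, 0.2, False), (1.5, 0.01, True)],
    )
    def test_boundaries(self, vip, fdr, kept):
        df = pd.DataFrame(
            {"feature_id": ["m"], "mean_a": [1.0], "mean_b": [2.0], "log2fc": [1.0],
             "p": [0.001], "fdr": [fdr], "call": ["up"], "vip": [vip]}
        )
        assert (len(call_dams(df)) == 1) is kept

    def test_matches_bruteforce_filter(self, rng):
        n = 200
        df = pd.DataFrame(
            {"feature_id": [f"m{i}" for i in range(n)],
             "mean_a": 1.0, "mean_b": 2.0, "log2fc": 1.0,
             "p": rng.uniform(size=n), "fdr": rng.uniform(size=n),
             "call": "up", "vip": rng.uniform(0, 2.5, size=n)}
        )
        cfg = ThresholdConfig()
        got = set(call_dams(df, cfg)["feature_id"])
        expected = {
            f"m{i}" for i in range(n)
            if df["vip"][i] > cfg.vip_cut and df["fdr"][i] < cfg.fdr_metab
        }
        assert got == expected


class TestTwoWayAnova:
    def test_constant_response(self):
        a = ["x", "x", "y", "y"] * 4
        b = ["u", "v"] * 8
        res = two_way_anova([3.0] * 16, a, b)
        assert all(F == 0.0 and p == 1.0 for F, p in res.values())

    def test_additive_construction(self, rng):
        levels_a, levels_b, reps = 2, 4, 6
        y, fa, fb = [], [], []
        eff_a = {0: 0.0, 1: 3.0}
        eff_b = {j: 0.5 * j for j in range(levels_b)}
        for i in range(levels_a):
            for j in range(levels_b):
                for _ in range(reps):
                    y.append(eff_a[i] + eff_b[j] + 1e-6 * rng.normal())
                    fa.append(f"a{i}")
                    fb.append(f"b{j}")
        res = two_way_anova(y, fa, fb)
        assert res["A"][1] < 1e-10 and res["B"][1] < 1e-10
        # interaction holds only noise: F is O(1), nowhere near significance
        assert res["A:B"][1] > 0.01

    def test_matches_projection_matrix_oracle(self, rng):
        """Balanced 2x4 with 6 reps: F values from explicit OLS projections."""
        y, fa, fb = [], [], []
        for i in range(2):
            for j in range(4):
                for _ in range(6):
                    y.append(rng.normal(i + 0.3 * j + 0.2 * i * j, 1.0))
                    fa.append(i)
                    fb.append(j)
        y = np.array(y)

        def dummies(labels):
            levels = sorted(set(labels))
            return np.column_stack([[1.0 if l == lv else 0.0 for l in labels]
                                    for lv in levels[1:]])

        one = np.ones((len(y), 1))
        A, B = dummies(fa), dummies(fb)
        AB = np.column_stack([A[:, i:i+1] * B[:, j:j+1]
                              for i in range(A.shape[1]) for j in range(B.shape[1])])

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return r @ r

        full = np.hstack([one, A, B, AB])
        rss_full = rss(full)
        df_resid = len(y) - full.shape[1]
        ms_resid = rss_full / df_resid
        # type-II: each term against the model with the term removed (no interaction
        # when testing a main effect)
        ss_a = rss(np.hstack([one, B])) - rss(np.hstack([one, A, B]))
        ss_b = rss(np.hstack([one, A])) - rss(np.hstack([one, A, B]))
        ss_ab = rss(np.hstack([one, A, B])) - rss_full
        oracle = {
            "A": ss_a / A.shape[1] / ms_resid,
            "B": ss_b / B.shape[1] / ms_resid,
            "A:B": ss_ab / AB.shape[1] / ms_resid,
        }
        res = two_way_anova(y, fa, fb)
        for term in oracle:
            assert res[term][0] == pytest.approx(oracle[term], abs=1e-8)

    def test_empty_cell_is_listed(self):
        a = ["x", "x", "y"]
        b = ["u", "v", "u"]
        with pytest.raises(TriomicsError, match="empty design cell"):
            two_way_anova([1.0, 2.0, 3.0], a, b)


def test_vip_table_calls_require_both_gates(rng):
    # strong separation on half the features
    n = 40
    A = rng.lognormal(3, 0.1, size=(n, 6))
    B = A.copy() * np.where(np.arange(n)[:, None] < 20, 3.0, 1.0)
    m = OmicsMatrix(
        pd.DataFrame(np.hstack([A, B]), index=[f"m{i}" for i in range(n)],
                     columns=[f"s{j}" for j in range(12)]),
        "abundance",
    )
    res = vip_table(m, [f"s{j}" for j in range(6)], [f"s{j}" for j in range(6, 12)])
    called = res.loc[res["call"] != "ns"]
    assert (called["vip"] > 1.0).all() and (called["fdr"] < 0.05).all()
    assert set(called["feature_id"]) <= {f"m{i}" for i in range(20)}
    assert len(called) >= 15
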
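"""Nested permutation MANOVA, Wilks MANOVA, and discriminant analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

import chcevol as c
from chcevol.multivariate import ss_partition


def flat_design(outer):
    outer = np.asarray(outer, dtype=object)
    return c.NestedDesign(outer=outer, inner=outer.copy())


class TestSsPartition:
    def test_hand_partition_two_groups(self):
        """Groups {0,1} and {2,3}: between-SS 4, within-SS 1, F = 8."""
        X = np.array([0.0, 1.0, 2.0, 3.0])
        d = flat_design(["a", "a", "b", "b"])
        ss, df = ss_partition(X.reshape(-1, 1), d)
        assert ss["outer"] == pytest.approx(4.0)
        assert ss["residual"] == pytest.approx(1.0)
        res = c.nested_perm_manova(X, d, n_perm=49, seed=0)
        assert res.F_outer == pytest.approx(8.0)
        assert res.F_inner is None

    def test_components_sum_to_total(self, rng):
        for _ in range(20):
            X = rng.normal(size=(24, 3))
            d = c.NestedDesign(
                outer=np.repeat(["a", "b", "c"], 8),
                inner=np.repeat([f"{o}{i}" for o in "abc" for i in (1, 2)], 4),
            )
            ss, _ = ss_partition(X, d)
            assert ss["outer"] + ss["inner"] + ss["residual"] == pytest.approx(
                ss["total"], abs=1e-8
            )
            assert min(ss.values()) >= -1e-10

    def test_invariant_to_ordering_and_rotation(self, rng):
        X = rng.normal(size=(18, 3))
        outer = np.repeat(["a", "b", "c"], 6)
        inner = np.repeat(["a1", "a2", "b1", "b2", "c1", "c2"], 3)
        d = c.NestedDesign(outer=outer, inner=inner)
        ss, _ = ss_partition(X, d)
        perm = rng.permutation(18)
        ss_p, _ = ss_partition(X[perm], c.NestedDesign(outer=outer[perm],
                                                       inner=inner[perm]))
        Q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        ss_r, _ = ss_partition(X @ Q, d)
        for k in ss:
            assert ss_p[k] == pytest.approx(ss[k], abs=1e-8)
            assert ss_r[k] == pytest.approx(ss[k], abs=1e-8)


class TestNestedPermManova:
    def test_degenerate_constant_data(self):
        X = np.ones((8, 2))
        d = flat_design(list("aabbccdd"))
        res = c.nested_perm_manova(X, d, n_perm=9, seed=0)
        assert res.degenerate

    def test_paper_shaped_design_df(self, lct, nested_design):
        """9 species, 17 populations: outer df 8, inner df 8."""
        res = c.nested_perm_manova(lct, nested_design, n_perm=99, seed=3)
        assert res.df["outer"] == 8
        assert res.df["inner"] == 8
        assert res.p_outer <= 0.05  # strong species structure by construction
        assert res.p_inner is not None

    def test_exact_inner_p_matches_enumeration_oracle(self, rng):
        """Small design: exact inner p equals a brute-force enumeration."""
        outer = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
        inner = np.array(["a1", "a1", "a2", "a2", "b1", "b1", "b2", "b2"],
                         dtype=object)
        X = rng.normal(size=(8, 2))
        d = c.NestedDesign(outer=outer, inner=inner)
        res = c.nested_perm_manova(X, d, exact=True)

        # independent oracle: recompute F_inner for all within-species
        # rearrangements of population labels over individuals
        def f_inner(labels):
            ss, df = ss_partition(X, c.NestedDesign(outer=outer,
                                                    inner=np.array(labels)))
            return (ss["inner"] / df["inner"]) / (
                ss["residual"] / df["residual"]
            )

        obs = f_inner(inner)
        fs = []
        for pa in set(itertools.permutations(inner[:4])):
            for pb in set(itertools.permutations(inner[4:])):
                fs.append(f_inner(list(pa) + list(pb)))
        expected = np.mean(np.array(fs) >= obs - 1e-12)
        assert res.p_inner == pytest.approx(expected, abs=1e-12)

    def test_exact_outer_p_matches_enumeration_oracle(self, rng):
        """Outer test permutes whole populations between species."""
        outer = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
        inner = np.array(["u1", "u1", "u2", "u2", "u3", "u3", "u4", "u4"],
                         dtype=object)
        X = rng.normal(size=(8, 1))
        X[:4] += 1.5
        d = c.NestedDesign(outer=outer, inner=inner)
        res = c.nested_perm_manova(X, d, exact=True)

        def f_outer(unit_species):
            lab = {u: s for u, s in zip(["u1", "u2", "u3", "u4"], unit_species)}
            o = np.array([lab[u] for u in inner], dtype=object)
            ss, df = ss_partition(X, c.NestedDesign(outer=o, inner=inner))
            return (ss["outer"] / df["outer"]) / (ss["inner"] / df["inner"])

        obs = f_outer(["a", "a", "b", "b"])
        fs = [f_outer(p)
              for p in set(itertools.permutations(["a", "a", "b", "b"]))]
        expected = np.mean(np.array(fs) >= obs - 1e-12)
        assert res.p_outer == pytest.approx(expected, abs=1e-12)

    def test_seed_required_and_reproducible(self, rng):
        X = rng.normal(size=(12, 2))
        d = flat_design(list("aaaabbbbcccc"))
        with pytest.raises(c.InvalidInputError, match="seed"):
            c.nested_perm_manova(X, d, n_perm=9)
        r1 = c.nested_perm_manova(X, d, n_perm=49, seed=5)
        r2 = c.nested_perm_manova(X, d, n_perm=49, seed=5)
        assert r1.p_outer == r2.p_outer

    def test_p_floor_is_one_over_nperm_plus_one(self, rng):
        X = np.concatenate([rng.normal(size=10), rng.normal(8.0, 1, size=10)])
        d = flat_design(["a"] * 10 + ["b"] * 10)
        res = c.nested_perm_manova(X, d, n_perm=99, seed=1)
        assert res.p_outer == pytest.approx(1 / 100)


class TestWilks:
    def test_univariate_two_group_matches_t_statistic(self, rng):
        x = np.concatenate([rng.normal(size=12), rng.normal(1.0, 1, size=12)])
        g = np.array(["a"] * 12 + ["b"] * 12)
        t, _ = stats.ttest_ind(x[:12], x[12:])
        res = c.wilks_manova(x.reshape(-1, 1), g)
        assert res.lambda_ == pytest.approx(1 / (1 + t * t / 22), rel=1e-10)
        assert res.approx_F == pytest.approx(t * t, rel=1e-8)

    def test_matches_statsmodels_manova(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        X = rng.normal(size=(30, 3))
        X[10:20] += 0.8
        g = np.repeat(["a", "b", "c"], 10)
        df = pd.DataFrame(X, columns=["x1", "x2", "x3"])
        df["g"] = g
        ref = MANOVA.from_formula("x1 + x2 + x3 ~ g", data=df).mv_test()
        stat = ref.results["g"]["stat"].loc["Wilks' lambda"]
        res = c.wilks_manova(X, g)
        assert res.lambda_ == pytest.approx(float(stat["Value"]), rel=1e-8)
        assert res.approx_F == pytest.approx(float(stat["F Value"]), rel=1e-8)
        assert res.p == pytest.approx(float(stat["Pr > F"]), abs=1e-10)

    def test_lambda_equals_eigenvalue_product(self, rng):
        X = rng.normal(size=(40, 4))
        X[:20] += 0.5
        g = np.repeat(["a", "b"], 20)
        res = c.wilks_manova(X, g)
        d = c.discriminant_analysis(X, g)
        prod = np.prod(1.0 / (1.0 + d.eigenvalues))
        assert res.lambda_ == pytest.approx(prod, rel=1e-8)

    def test_null_lambda_near_one(self, rng):
        lams = []
        for _ in range(30):
            X = rng.normal(size=(60, 2))
            g = np.repeat(["a", "b"], 30)
            lams.append(c.wilks_manova(X, g).lambda_)
        assert np.mean(lams) > 0.9

    def test_singular_within_matrix_raises(self):
        X = np.zeros((6, 3))
        X[:, 0] = [0, 1, 2, 3, 4, 5]
        g = np.repeat(["a", "b"], 3)
        with pytest.raises(c.NumericalError, match="singular"):
            c.wilks_manova(X, g)


class TestDiscriminant:
    def test_two_groups_single_function(self, rng):
        X = rng.normal(size=(30, 4))
        X[:15] += 1.0
        g = np.repeat(["a", "b"], 15)
        d = c.discriminant_analysis(X, g)
        assert d.loadings.shape[0] == 1
        assert d.pct_between_variance[0] == pytest.approx(1.0)

    def test_separating_coordinate_dominates_loading(self, rng):
        X = rng.normal(size=(60, 3), scale=0.2)
        X[:30, 0] += 5.0
        g = np.repeat(["a", "b"], 30)
        d = c.discriminant_analysis(X, g)
        load = d.loadings.iloc[0].to_numpy()
        assert np.argmax(np.abs(load)) == 0

    def test_eigenvalues_match_generalized_eigenproblem(self, rng):
        from chcevol.multivariate import _scatter_matrices

        X = rng.normal(size=(50, 4))
        X[:25] += 0.7
        X[25:, 1] -= 0.5
        g = np.repeat(["a", "b"], 25)
        W, B, *_ = _scatter_matrices(X, np.asarray(g, dtype=object))
        ref = np.sort(np.real(linalg.eig(B, W)[0]))[::-1]
        d = c.discriminant_analysis(X, g)
        np.testing.assert_allclose(d.eigenvalues, ref[: len(d.eigenvalues)],
                                   atol=1e-8)

    def test_matches_sklearn_explained_variance(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = rng.normal(size=(45, 3))
        X[15:30] += 1.0
        X[30:, 2] += 2.0
        g = np.repeat(["a", "b", "c"], 15)
        lda = LinearDiscriminantAnalysis(solver="eigen").fit(X, g)
        d = c.discriminant_analysis(X, g)
        np.testing.assert_allclose(
            d.pct_between_variance, lda.explained_variance_ratio_, atol=1e-8
        )


class TestVariancePartition:
    def test_all_between_outer(self):
        X = np.repeat([0.0, 10.0], 6)
        d = flat_design(["a"] * 6 + ["b"] * 6)
        vp = c.variance_partition(X, d)
        assert vp["outer"] == pytest.approx(1.0)
        assert vp["residual"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_example_outer_fraction(self):
        X = np.array([0.0, 1.0, 2.0, 3.0])
        vp = c.variance_partition(X, flat_design(["a", "a", "b", "b"]))
        assert vp["outer"] == pytest.approx(0.8)

    def test_fractions_sum_to_one_random(self, rng):
        outer = np.repeat(["a", "b", "c"], 8)
        inner = np.repeat([f"{o}{i}" for o in "abc" for i in (1, 2)], 4)
        for _ in range(100):
            X = rng.normal(size=(24, 2))
            vp = c.variance_partition(X, c.NestedDesign(outer=outer, inner=inner))
            assert vp["outer"] + vp["inner"] + vp["residual"] == pytest.approx(1.0)

    def test_degenerate_flag(self):
        vp = c.variance_partition(np.ones(6), flat_design(list("aabbcc")))
        assert vp["degenerate"]
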
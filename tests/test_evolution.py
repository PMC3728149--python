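"""Brownian likelihood and the nine-model maximum-likelihood framework."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import chcevol as c
from chcevol.evolution import (
    _punct_eval,
    _punct_node_info,
    _fit_punctuated,
)
from chcevol.trees import transform_tree, yule_tree


def tip_array(tree, rng, scale=1.0):
    return {l: float(rng.normal(scale=scale)) for l in tree.tip_labels}


class TestBmLoglik:
    def test_two_tip_star_standard_normals(self):
        t = c.read_newick("(A:1,B:1);")
        lnl = c.bm_loglik(t, {"A": 0.0, "B": 0.0}, rate=1.0, root_state=0.0)
        assert lnl == pytest.approx(-math.log(2 * math.pi), abs=1e-10)

    def test_pruning_equals_direct(self, rng):
        for _ in range(40):
            t = yule_tree(int(rng.integers(3, 9)), rng=rng,
                          ultrametric=False, depth=None)
            x = tip_array(t, rng)
            rate = float(rng.uniform(0.2, 3.0))
            mu = float(rng.normal())
            l1 = c.bm_loglik(t, x, rate, mu, method="pruning")
            l2 = c.bm_loglik(t, x, rate, mu, method="direct")
            assert l1 == pytest.approx(l2, abs=1e-8)

    def test_length_rate_tradeoff(self, rng):
        """Doubling branch lengths and halving sigma^2 leaves lnL unchanged."""
        t = yule_tree(6, rng=rng)
        x = tip_array(t, rng)
        l1 = c.bm_loglik(t, x, rate=1.0, root_state=0.0)
        doubled = t.clone()
        for n in doubled._flatten()["preorder"]:
            if n is not doubled.root:
                n.length *= 2
        doubled._flat = None
        l2 = c.bm_loglik(doubled, x, rate=0.5, root_state=0.0)
        assert l1 == pytest.approx(l2, abs=1e-10)

    def test_zero_path_conditioning(self):
        """A tip joined to the root by zero-length edges is a point mass."""
        t = c.read_newick("(A:0,B:1);")
        ok = c.bm_loglik(t, {"A": 0.5, "B": 1.0}, rate=1.0, root_state=0.5)
        assert math.isfinite(ok)
        bad = c.bm_loglik(t, {"A": 0.4, "B": 1.0}, rate=1.0, root_state=0.5)
        assert bad == -math.inf

    def test_invalid_rate(self):
        t = c.read_newick("(A:1,B:1);")
        with pytest.raises(c.InvalidInputError):
            c.bm_loglik(t, {"A": 0, "B": 0}, rate=0.0, root_state=0.0)


class TestParameterCounts:
    def test_nine_tip_counts_match_framework(self):
        """On 9 tips: free-tempo P = 16 / 9 / 8; single-rate models P = 1."""
        for pc, tempo, expected in [
            ("pure_phylogenetic", "free", 16),
            ("nonphylogenetic", "free", 9),
            ("punctuated", "free", 8),
            ("pure_phylogenetic", "distance", 1),
            ("nonphylogenetic", "equal", 1),
            ("punctuated", "distance", 1),
        ]:
            assert c.n_params(c.ModelSpec(pc, tempo), 9) == expected

    def test_general_free_counts(self):
        for n in (5, 12):
            assert c.n_params(c.ModelSpec("pure_phylogenetic", "free"), n) == 2 * n - 2
            assert c.n_params(c.ModelSpec("nonphylogenetic", "free"), n) == n
            assert c.n_params(c.ModelSpec("punctuated", "free"), n) == n - 1


class TestClosedFormFits:
    def test_nonphylo_equal_is_iid_normal_mle(self):
        t = c.read_newick("((A:1,B:1):1,C:2);")
        fit = c.fit_model(t, {"A": -1.0, "B": 0.0, "C": 1.0},
                          c.ModelSpec("nonphylogenetic", "equal"))
        assert fit.root_state == pytest.approx(0.0, abs=1e-10)
        assert fit.rate == pytest.approx(2 / 3, rel=1e-10)
        assert fit.lnL == pytest.approx(-3.64862, abs=1e-5)
        assert fit.aic == pytest.approx(9.29723, abs=1e-5)
        assert fit.n_params == 1

    def test_punctuated_equal_two_tips(self):
        t = c.read_newick("(A:1,B:1);")
        fit = c.fit_model(t, {"A": 0.0, "B": 1.0},
                          c.ModelSpec("punctuated", "equal"))
        assert fit.lnL == pytest.approx(-1.41894, abs=1e-5)
        # by symmetry the fixed assignment gives the same likelihood
        fixed = c.fit_model(t, {"A": 0.0, "B": 1.0},
                            c.ModelSpec("punctuated", "equal"),
                            punct_assignment="fixed")
        assert fixed.lnL == pytest.approx(fit.lnL, abs=1e-10)

    def test_zero_variance_rejected(self):
        t = c.read_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(c.NumericalError, match="unbounded"):
            c.fit_model(t, {"A": 1.0, "B": 1.0, "C": 1.0},
                        c.ModelSpec("punctuated", "equal"))

    def test_aic_arithmetic(self, rng):
        t = yule_tree(7, rng=rng)
        x = tip_array(t, rng)
        for spec in c.ALL_MODELS:
            fit = c.fit_model(t, x, spec, seed=0, n_starts=3)
            assert fit.aic == pytest.approx(
                -2 * fit.lnL + 2 * fit.n_params, abs=1e-10
            )


class TestPunctuated:
    def test_factorized_free_likelihood_matches_pruning(self, rng):
        """The closed-form punctuated/free profile equals a pruning pass on
        the transformed tree with the fitted branch lengths."""
        for _ in range(10):
            t = yule_tree(int(rng.integers(3, 8)), rng=rng)
            x = np.array([rng.normal() for _ in range(t.n_tips)])
            n_int = len(t.internal_nodes)
            bits = tuple(int(b) for b in rng.integers(0, 2, size=n_int))
            info = _punct_node_info(t)
            lnL, _, mu, b, boundary = _punct_eval(
                t, x, c.ModelSpec("punctuated", "free"), info, bits, 1e-9
            )
            if boundary:
                continue
            pt = transform_tree(t, "punctuated", "free",
                                branch_params=b, punct_assignment=bits)
            ref = c.bm_loglik(pt, dict(zip(t.tip_labels, x)), rate=1.0,
                              root_state=mu)
            assert lnL == pytest.approx(ref, abs=1e-8)

    def test_hillclimb_matches_exhaustive(self, rng):
        """Forcing the hill-climb path reproduces the exhaustive maximum."""
        t = yule_tree(8, rng=rng)
        x = np.array([rng.normal() for _ in range(8)])
        spec = c.ModelSpec("punctuated", "equal")
        info = _punct_node_info(t)
        exhaustive = _fit_punctuated(t, x, spec, 1e-6, seed=0,
                                     max_exhaustive=15)
        climbed = _fit_punctuated(t, x, spec, 1e-6, seed=0, max_exhaustive=0)
        assert climbed.lnL == pytest.approx(exhaustive.lnL, abs=1e-9)

    def test_max_assignment_dominates_fixed(self, rng):
        t = yule_tree(7, rng=rng)
        x = tip_array(t, rng)
        for tempo in ("distance", "equal", "free"):
            spec = c.ModelSpec("punctuated", tempo)
            mx = c.fit_model(t, x, spec, punct_assignment="max")
            fx = c.fit_model(t, x, spec, punct_assignment="fixed")
            assert mx.lnL >= fx.lnL - 1e-9


class TestNesting:
    def test_free_tempo_dominates_within_class(self, rng):
        for _ in range(8):
            t = yule_tree(int(rng.integers(4, 9)), rng=rng)
            x = tip_array(t, rng)
            for pc in ("pure_phylogenetic", "nonphylogenetic", "punctuated"):
                fits = {
                    tempo: c.fit_model(t, x, c.ModelSpec(pc, tempo),
                                       seed=0, n_starts=3)
                    for tempo in ("distance", "equal", "free")
                }
                assert fits["free"].lnL >= fits["distance"].lnL - 1e-8
                assert fits["free"].lnL >= fits["equal"].lnL - 1e-8

    def test_ultrametric_nonphylo_distance_equals_equal(self, rng):
        """On an ultrametric tree the rate absorbs the common tip depth."""
        t = yule_tree(8, rng=rng, ultrametric=True, depth=2.0)
        x = tip_array(t, rng)
        f1 = c.fit_model(t, x, c.ModelSpec("nonphylogenetic", "distance"))
        f2 = c.fit_model(t, x, c.ModelSpec("nonphylogenetic", "equal"))
        assert f1.aic == pytest.approx(f2.aic, abs=1e-8)


class TestAicTable:
    def test_single_trait_has_one_zero_delta(self, rng):
        # non-ultrametric tree: avoids the exact nonphylo distance/equal tie
        t = yule_tree(6, rng=rng, ultrametric=False, depth=None)
        row = pd.DataFrame(
            {l: [float(rng.normal())] for l in t.tip_labels}, index=["tr"]
        )
        table = c.aic_model_table(t, row, seed=0, n_starts=3)
        valid = table.delta_aic.loc["tr"].dropna()
        assert (valid == 0).sum() == 1
        assert (valid >= -1e-12).all()
        assert table.best_model["tr"] in valid.index

    def test_boundary_free_fits_excluded_from_ranking(self, rng):
        t = yule_tree(6, rng=rng)
        row = pd.DataFrame(
            {l: [float(rng.normal())] for l in t.tip_labels}, index=["tr"]
        )
        table = c.aic_model_table(t, row, seed=0, n_starts=3)
        assert bool(table.boundary.loc["tr", "nonphylo/free"])
        assert math.isnan(table.delta_aic.loc["tr", "nonphylo/free"])

    def test_errors_isolated_per_trait(self, rng):
        t = yule_tree(5, rng=rng)
        rows = pd.DataFrame(
            {l: [1.0, float(rng.normal())] for l in t.tip_labels},
            index=["flat", "ok"],
        )
        table = c.aic_model_table(t, rows, seed=0, n_starts=3)
        assert table.best_model["flat"] is None
        assert table.errors["flat"]
        assert table.best_model["ok"] is not None


class TestRecoveryQuick:
    def test_sigma2_consistent_under_brownian_motion(self):
        """sigma^2-hat relative bias stays small on a 32-tip tree."""
        t = yule_tree(32, seed=9)
        est = []
        for rep in range(100):
            x = c.simulate_trait(t, "pure_phylogenetic", "distance",
                                 rate=2.0, seed=100 + rep)
            fit = c.fit_model(t, x, c.ModelSpec("pure_phylogenetic", "distance"))
            est.append(fit.rate)
        assert abs(np.mean(est) / 2.0 - 1.0) < 0.08
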
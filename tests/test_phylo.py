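"""Tests for phylogenetic signal, model comparison, regressions and the
phylomorphospace.

Independent oracles: a literal matrix-algebra transcription of the K
formula, a hand-built Abouheif proximity matrix, R's phytools (via
Rscript) for Blomberg's K, and classical OLS/ANOVA in the star-tree
limits.
"""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from necknet import (
    abouheif_cmean,
    blomberg_k,
    dpgls,
    fit_evo_models,
    generate_tree,
    kmult,
    pgls,
    phylomorphospace,
    read_tree,
    simulate_traits,
)
from necknet.phylo import _eb_transform, _mvn_phylo_loglik

FIVE_TIP = "(((A:1,B:1):1,(C:1.5,D:1.5):0.5):1,E:3);"


def k_formula_oracle(C, y):
    """Literal transcription of the K formula with explicit matrix algebra."""
    n = len(y)
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    a = (ones @ Cinv @ y) / (ones @ Cinv @ ones)
    r = y - a * ones
    mse0 = (r @ r) / (n - 1)
    mse = (r @ Cinv @ r) / (n - 1)
    expected = (np.trace(C) - n / (ones @ Cinv @ ones)) / (n - 1)
    return (mse0 / mse) / expected


class TestBlombergK:
    def test_matches_formula_transcription_on_five_tips(self):
        tree = read_tree(FIVE_TIP)
        y = pd.Series({"A": 1.0, "B": 1.4, "C": 3.0, "D": 2.5, "E": -1.0})
        C = tree.vcv(order=list(y.index))
        res = blomberg_k(tree, y, n_perm=9, seed=0)
        assert res.statistic == pytest.approx(
            k_formula_oracle(C, y.to_numpy()), abs=1e-10)

    def test_matches_phytools_reference(self):
        """Cross-check against the independent R implementation."""
        script = textwrap.dedent("""
            suppressMessages(library(phytools))
            tree <- read.tree(text="(((A:1,B:1):1,(C:1.5,D:1.5):0.5):1,E:3);")
            x <- c(A=1.0, B=1.4, C=3.0, D=2.5, E=-1.0)
            cat(sprintf("%.12f", as.numeric(phylosig(tree, x, method="K"))))
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        expected = float(out.stdout.strip())
        tree = read_tree(FIVE_TIP)
        y = pd.Series({"A": 1.0, "B": 1.4, "C": 3.0, "D": 2.5, "E": -1.0})
        assert blomberg_k(tree, y, n_perm=9, seed=0).statistic == (
            pytest.approx(expected, abs=1e-8))

    def test_bm_simulations_center_near_one(self):
        """K averages ~1 for Brownian traits (reduced-size check)."""
        tree = generate_tree(100, seed=1)
        sims = simulate_traits(tree, "BM", n_traits=150, seed=2)
        C = tree.vcv(order=list(sims.index))
        ks = [k_formula_oracle(C, sims[c].to_numpy()) for c in sims]
        # verify implementation agrees with oracle on a subsample
        for c in list(sims)[:5]:
            assert blomberg_k(tree, sims[c], n_perm=9, seed=0).statistic == (
                pytest.approx(k_formula_oracle(C, sims[c].to_numpy()),
                              abs=1e-10))
        assert 0.9 <= np.mean(ks) <= 1.1

    def test_tree_free_noise_gives_low_k(self):
        def balanced(depth):
            if depth == 0:
                balanced.i += 1
                return f"t{balanced.i}:1"
            return f"({balanced(depth - 1)},{balanced(depth - 1)}):1"

        balanced.i = 0
        tree = read_tree(balanced(5) + ";")  # 32 tips
        rng = np.random.default_rng(3)
        below = 0
        n_rep = 200
        for _ in range(n_rep):
            y = pd.Series(rng.standard_normal(32), index=tree.tip_labels)
            if blomberg_k(tree, y, n_perm=9, seed=0).statistic < 1:
                below += 1
        assert below / n_rep >= 0.95

    def test_zero_variance_rejected(self, balanced8):
        y = pd.Series(1.0, index=balanced8.tip_labels)
        with pytest.raises(ValueError, match="variance"):
            blomberg_k(balanced8, y)

    def test_invariant_to_tip_order(self, balanced8):
        rng = np.random.default_rng(5)
        y = pd.Series(rng.standard_normal(8), index=balanced8.tip_labels)
        a = blomberg_k(balanced8, y, n_perm=99, seed=1)
        b = blomberg_k(balanced8, y.sample(frac=1, random_state=0),
                       n_perm=99, seed=1)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)


class TestKmult:
    def test_univariate_reduces_to_blomberg(self, balanced8):
        rng = np.random.default_rng(6)
        y = pd.Series(rng.standard_normal(8), index=balanced8.tip_labels,
                      name="t")
        km = kmult(balanced8, y.to_frame(), n_perm=9, seed=0)
        bk = blomberg_k(balanced8, y, n_perm=9, seed=0)
        assert km.statistic == pytest.approx(bk.statistic, abs=1e-10)

    def test_bm_simulations_center_near_one(self):
        tree = generate_tree(100, seed=4)
        vals = []
        for rep in range(60):
            Y = simulate_traits(tree, "BM", n_traits=3, seed=100 + rep)
            vals.append(kmult(tree, Y, n_perm=1, seed=0).statistic)
        assert 0.9 <= np.mean(vals) <= 1.1

    def test_shuffled_rows_give_uniformish_p(self):
        tree = generate_tree(32, seed=5)
        rng = np.random.default_rng(7)
        ps = []
        for rep in range(100):
            Y = simulate_traits(tree, "BM", n_traits=2, seed=200 + rep)
            Y.iloc[:, :] = Y.to_numpy()[rng.permutation(len(Y))]
            ps.append(kmult(tree, Y, n_perm=49, seed=rep).p_value)
        assert 0.25 < np.mean(ps) < 0.75


class TestAbouheif:
    def test_hand_computed_four_tip_matrix(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        A = tree.abouheif_proximity(order=["A", "B", "C", "D"])
        expected = np.array([
            [0, 1 / 2, 1 / 8, 1 / 8],
            [1 / 2, 0, 1 / 8, 1 / 8],
            [1 / 8, 1 / 8, 0, 1 / 2],
            [1 / 8, 1 / 8, 1 / 2, 0],
        ])
        np.testing.assert_allclose(A, expected)
        # Cmean evaluated by hand from the same matrix
        y = np.array([1.0, 2.0, 10.0, 11.0])
        z = y - y.mean()
        manual = len(y) * (z @ expected @ z) / (expected.sum() * (z @ z))
        res = abouheif_cmean(
            tree, pd.Series(y, index=["A", "B", "C", "D"]), n_perm=9, seed=0)
        assert res.statistic == pytest.approx(manual, abs=1e-12)

    def test_clade_structured_trait_is_significant(self, balanced8):
        y = pd.Series([0, 0.1, 0.2, 0.05, 5, 5.2, 5.1, 4.9],
                      index=balanced8.tip_labels)
        res = abouheif_cmean(balanced8, y, n_perm=999, seed=1)
        assert res.statistic > 0
        assert res.p_value <= 0.05

    def test_star_tree_flagged_degenerate(self):
        star = read_tree("(A:1,B:1,C:1,D:1);")
        y = pd.Series([1, 2, 3, 4.0], index=["A", "B", "C", "D"])
        with pytest.warns(UserWarning, match="degenerate"):
            abouheif_cmean(star, y, n_perm=9, seed=0)

    def test_pvalue_uses_count_plus_one_estimator(self, balanced8):
        rng = np.random.default_rng(9)
        y = pd.Series(rng.standard_normal(8), index=balanced8.tip_labels)
        res = abouheif_cmean(balanced8, y, n_perm=99, seed=2)
        assert 0 < res.p_value <= 1
        assert (res.p_value * 100) == pytest.approx(round(res.p_value * 100))


class TestEvoModels:
    def test_eb_at_vanishing_rate_equals_bm(self):
        tree = generate_tree(24, seed=8)
        Y = simulate_traits(tree, "BM", n_traits=2, seed=9).to_numpy()
        C = tree.vcv()
        ll_bm, _ = _mvn_phylo_loglik(Y, C)
        ll_eb, _ = _mvn_phylo_loglik(Y, _eb_transform(C, -1e-12))
        assert ll_eb == pytest.approx(ll_bm, abs=1e-6)

    def test_aic_weights_sum_to_one(self):
        tree = generate_tree(24, seed=10)
        Y = simulate_traits(tree, "BM", n_traits=2, seed=11)
        fits = fit_evo_models(tree, Y)
        assert sum(f.aic_weight for f in fits) == pytest.approx(1.0)
        assert {f.model for f in fits} == {"BM", "OU", "EB"}

    def test_bm_recovery(self):
        """BM wins the AIC comparison for most BM-simulated datasets."""
        tree = generate_tree(64, seed=12)
        wins = 0
        n_rep = 200
        for rep in range(n_rep):
            Y = simulate_traits(tree, "BM", n_traits=2, seed=1000 + rep)
            fits = fit_evo_models(tree, Y)
            best = max(fits, key=lambda f: f.aic_weight)
            wins += best.model == "BM"
        assert wins / n_rep >= 0.8

    def test_strong_ou_recovery(self):
        tree = generate_tree(64, seed=13)
        alpha = 20.0 / tree.depth
        wins = 0
        n_rep = 200
        for rep in range(n_rep):
            Y = simulate_traits(tree, "OU", alpha=alpha, n_traits=2,
                                seed=2000 + rep)
            fits = fit_evo_models(tree, Y)
            best = max(fits, key=lambda f: f.aic_weight)
            wins += best.model == "OU"
        assert wins / n_rep >= 0.8


class TestPGLS:
    def test_self_regression_is_perfect(self, tree48):
        x = simulate_traits(tree48, "BM", seed=14)["trait1"].rename("x")
        res = pgls(tree48, x.rename("y"), x)
        assert res.coefficients["x"] == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_star_tree_equals_ols(self):
        star = read_tree("(" + ",".join(f"t{i}:1" for i in range(20)) + ");")
        rng = np.random.default_rng(15)
        x = pd.Series(rng.standard_normal(20), index=star.tip_labels,
                      name="x")
        y = (2 * x + rng.standard_normal(20)).rename("y")
        res = pgls(star, y, x)
        X = np.column_stack([np.ones(20), x.to_numpy()])
        beta = np.linalg.lstsq(X, y.to_numpy(), rcond=None)[0]
        assert res.coefficients.to_numpy() == pytest.approx(beta, abs=1e-10)

    def test_null_type_one_error_near_nominal(self):
        tree = generate_tree(32, seed=16)
        rejections = 0
        n_rep = 1000
        for rep in range(n_rep):
            y = simulate_traits(tree, "BM", seed=3000 + rep)["trait1"]
            x = simulate_traits(tree, "BM", seed=9_000_000 + rep)["trait1"]
            res = pgls(tree, y.rename("y"), x.rename("x"))
            rejections += res.p_value < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_singular_design_rejected(self, tree48):
        x = simulate_traits(tree48, "BM", seed=17)["trait1"]
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="singular"):
            pgls(tree48, x.rename("y"), X)


class TestDPGLS:
    def test_star_tree_univariate_equals_anova(self):
        star = read_tree("(" + ",".join(f"t{i}:1" for i in range(16)) + ");")
        rng = np.random.default_rng(18)
        y = pd.DataFrame({"t": rng.standard_normal(16)},
                         index=star.tip_labels)
        g = pd.Series([0] * 8 + [1] * 8, index=star.tip_labels)
        res = dpgls(star, y, g, n_perm=9, seed=0)
        from scipy.stats import f_oneway

        f_classic = f_oneway(y["t"][g == 0], y["t"][g == 1]).statistic
        assert res.F == pytest.approx(f_classic, abs=1e-8)

    def test_clade_shift_detected(self, balanced8):
        Y = simulate_traits(balanced8, "BM", rate=0.01, n_traits=3, seed=19)
        g = pd.Series([1, 1, 1, 1, 0, 0, 0, 0], index=balanced8.tip_labels)
        Y.loc[g == 1] += 50.0
        res = dpgls(balanced8, Y, g, n_perm=999, seed=1)
        assert res.p_value <= 0.05  # smallest attainable on 8 tips is ~0.014

    def test_single_level_factor_rejected(self, balanced8):
        Y = simulate_traits(balanced8, "BM", n_traits=2, seed=20)
        g = pd.Series(1, index=balanced8.tip_labels)
        with pytest.raises(ValueError, match="single level"):
            dpgls(balanced8, Y, g)


class TestPhylomorphospace:
    def test_perfectly_correlated_traits_load_on_pc1(self, balanced8):
        x = simulate_traits(balanced8, "BM", seed=21)["trait1"]
        traits = pd.DataFrame({"a": x, "b": 3 * x + 1})
        res = phylomorphospace(balanced8, traits)
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_percent_variance_sums_to_100(self, tree48):
        Y = simulate_traits(tree48, "BM", n_traits=5, seed=22)
        res = phylomorphospace(tree48, Y)
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-9)
        assert res.node_scores.shape[1] == 5

    def test_constant_column_rejected(self, tree48):
        Y = simulate_traits(tree48, "BM", n_traits=2, seed=23)
        Y["c"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            phylomorphospace(tree48, Y)
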
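import numpy as np
import pandas as pd
import pytest

from mgc_ecoscreen import (
    DegenerateTraitError,
    blomberg_k,
    bm_loglik,
    compute_signal,
    fit_lambda,
    fritz_purvis_d,
    lambda_transform,
    parse_newick,
    phylo_pca,
    phylo_vcv,
    sim_binary_trait,
    sim_traits,
)
from mgc_ecoscreen.phylo_signal import lambda_max

from oracles import bm_loglik_dense, blomberg_k_dense, sister_diff_sum_recursive


class TestVcv:
    def test_star_tree_diagonal(self, star_tree):
        C = phylo_vcv(star_tree).C
        assert np.allclose(C, np.eye(3))

    def test_three_tip_entries(self, three_tip_tree):
        C = phylo_vcv(three_tip_tree).C
        labels = three_tip_tree.tip_labels
        a, b, c = (labels.index(t) for t in "ABC")
        assert C[a, a] == pytest.approx(2.0)
        assert C[a, b] == pytest.approx(1.0)
        assert C[a, c] == pytest.approx(0.0)

    def test_symmetric_psd(self, yule_tree_64):
        C = phylo_vcv(yule_tree_64).C
        assert np.allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() > -1e-10


class TestBmLoglik:
    def test_star_tree_mu_is_mean(self, star_tree):
        x = np.array([1.0, 2.0, 6.0])
        fit = bm_loglik(x, phylo_vcv(star_tree).C)
        assert fit.mu_hat == pytest.approx(x.mean())

    def test_constant_trait_rejected(self, three_tip_tree):
        with pytest.raises(DegenerateTraitError):
            bm_loglik(np.ones(3), phylo_vcv(three_tip_tree).C)

    def test_dense_oracle_equivalence(self, small_trees, rng):
        for tree in small_trees:
            C = phylo_vcv(tree).C
            x = rng.normal(0, 2, tree.n_tips) + 5
            fit = bm_loglik(x, C)
            mu, sigma2, ll = bm_loglik_dense(x, C)
            assert fit.mu_hat == pytest.approx(mu, abs=1e-8)
            assert fit.sigma2_hat == pytest.approx(sigma2, abs=1e-8)
            assert fit.loglik == pytest.approx(ll, abs=1e-8)


class TestLambda:
    def test_transform_endpoints(self, yule_tree_64):
        C = phylo_vcv(yule_tree_64).C
        assert np.allclose(lambda_transform(C, 1.0), C)
        assert np.allclose(lambda_transform(C, 0.0), np.diag(np.diag(C)))

    def test_lambda_max_keeps_pd(self, yule_tree_64):
        C = phylo_vcv(yule_tree_64).C
        hi = lambda_max(C)
        assert hi >= 1.0
        assert np.linalg.eigvalsh(lambda_transform(C, hi)).min() > -1e-8

    def test_ml_dominance(self, yule_tree_64, rng):
        C = phylo_vcv(yule_tree_64).C
        x = sim_traits(yule_tree_64, "lambda", 1.0, rng, lam=0.5)
        res = fit_lambda(x, C, n_sim=0)
        assert res.loglik >= res.loglik0 - 1e-9
        assert res.loglik >= bm_loglik(x, C).loglik - 1e-9

    def test_profile_loglik_matches_dense_oracle(self, small_trees, rng):
        for tree in small_trees:
            C = phylo_vcv(tree).C
            x = rng.normal(0, 1, tree.n_tips)
            for lam in (0.0, 0.3, 0.7, 1.0):
                ll = bm_loglik(x, lambda_transform(C, lam)).loglik
                _, _, ll_oracle = bm_loglik_dense(x, lambda_transform(C, lam))
                assert ll == pytest.approx(ll_oracle, abs=1e-8)

    def test_grid_estimate_matches_optimizer(self, yule_tree_64, rng):
        # the optimizer's lambda-hat maximizes the same profile the dense
        # grid sees: grid maximum is never above the optimizer's by more
        # than grid resolution effects
        C = phylo_vcv(yule_tree_64).C
        x = sim_traits(yule_tree_64, "lambda", 1.0, rng, lam=0.6)
        res = fit_lambda(x, C, n_sim=0)
        grid = np.linspace(0, 1, 201)
        grid_ll = [bm_loglik(x, lambda_transform(C, l)).loglik for l in grid]
        assert res.loglik >= max(grid_ll) - 1e-6

    def test_recovery_bias_small(self):
        # lambda-hat on data simulated at lambda in {0, 0.5, 1}
        rng = np.random.default_rng(7)
        from mgc_ecoscreen import sim_tree

        for true_lam in (0.0, 0.5, 1.0):
            hats = []
            for r in range(40):
                tree = sim_tree(200, seed=5000 + r)
                x = sim_traits(tree, "lambda", 1.0, rng, lam=true_lam)
                hats.append(fit_lambda(x, tree, n_sim=0).lambda_hat)
            assert abs(np.mean(hats) - true_lam) < 0.05


class TestBlombergK:
    def test_three_tip_dense_oracle(self, three_tip_tree):
        x = np.array([1.0, 2.0, 4.0])
        C = phylo_vcv(three_tip_tree).C
        k, _ = blomberg_k(x, C, n_perm=0)
        assert k == pytest.approx(blomberg_k_dense(x, C), abs=1e-8)

    def test_dense_oracle_all_small_trees(self, small_trees, rng):
        for tree in small_trees:
            C = phylo_vcv(tree).C
            x = rng.normal(size=tree.n_tips)
            k, _ = blomberg_k(x, C, n_perm=0)
            assert k == pytest.approx(blomberg_k_dense(x, C), abs=1e-8)

    def test_affine_invariance(self, yule_tree_64, rng):
        C = phylo_vcv(yule_tree_64).C
        x = sim_traits(yule_tree_64, "brownian", 1.0, rng)
        k1, _ = blomberg_k(x, C, n_perm=0)
        k2, _ = blomberg_k(3.7 * x - 11.0, C, n_perm=0)
        assert k1 == pytest.approx(k2, rel=1e-10)

    def test_permutation_p_seeded_reproducible(self, yule_tree_64):
        x = sim_traits(yule_tree_64, "brownian", 1.0, seed=3)
        p1 = blomberg_k(x, yule_tree_64, n_perm=99, seed=11)[1]
        p2 = blomberg_k(x, yule_tree_64, n_perm=99, seed=11)[1]
        assert p1 == p2 and 0.0 < p1 <= 1.0


class TestFritzPurvisD:
    def test_four_tip_split_by_clade(self, balanced_four):
        labels = balanced_four.tip_labels
        x = np.array([1.0 if t in ("A", "B") else 0.0 for t in labels])
        d_obs = sister_diff_sum_recursive(balanced_four, x)
        assert d_obs == pytest.approx(1.0)  # only the root contributes |1-0|
        res = fritz_purvis_d(x, balanced_four, n_sim=50, seed=0)
        assert res.d_obs == pytest.approx(1.0)

    def test_d_obs_matches_recursion_on_fixtures(self, small_trees, rng):
        for tree in small_trees:
            if tree.n_tips < 4:
                continue
            x = np.zeros(tree.n_tips)
            x[rng.choice(tree.n_tips, size=tree.n_tips // 2, replace=False)] = 1.0
            if x.sum() in (0, tree.n_tips):
                continue
            res = fritz_purvis_d(x, tree, n_sim=20, seed=1)
            assert res.d_obs == pytest.approx(
                sister_diff_sum_recursive(tree.resolve_polytomies(), x), abs=1e-8
            )

    def test_label_swap_invariance(self, yule_tree_64):
        x = sim_binary_trait(yule_tree_64, 0.4, "shuffle", seed=5)
        a = fritz_purvis_d(x, yule_tree_64, n_sim=30, seed=9)
        b = fritz_purvis_d(1.0 - x, yule_tree_64, n_sim=30, seed=9)
        assert a.d_obs == pytest.approx(b.d_obs)

    def test_invariant_trait_rejected(self, yule_tree_64):
        with pytest.raises(DegenerateTraitError):
            fritz_purvis_d(np.ones(64), yule_tree_64, n_sim=10, seed=0)

    def test_polytomy_resolution_deterministic(self):
        tree = parse_newick("(A:1,B:1,C:1,D:1);")
        x = np.array([1.0, 1.0, 0.0, 0.0])
        r1 = fritz_purvis_d(x, tree, n_sim=20, seed=2)
        r2 = fritz_purvis_d(x, tree, n_sim=20, seed=2)
        assert r1.d_obs == r2.d_obs == pytest.approx(
            sister_diff_sum_recursive(tree.resolve_polytomies(), x)
        )


class TestPhyloPca:
    def _traits(self, tree, rng, p=4):
        X = np.column_stack([
            sim_traits(tree, "brownian", 1.0, rng) for _ in range(p)
        ])
        return pd.DataFrame(X, index=tree.tip_labels,
                            columns=[f"t{i}" for i in range(p)])

    def test_eigenvalue_sum_equals_trace(self, yule_tree_64, rng):
        X = self._traits(yule_tree_64, rng)
        res = phylo_pca(X, yule_tree_64)
        C = phylo_vcv(yule_tree_64).C
        Cinv = np.linalg.inv(C)
        one = np.ones(len(X))
        a = (one @ Cinv @ X.to_numpy()) / (one @ Cinv @ one)
        Z = X.to_numpy() - a
        R = Z.T @ Cinv @ Z / (len(X) - 1)
        assert res.eigenvalues.sum() == pytest.approx(np.trace(R))

    def test_star_tree_matches_ordinary_pca(self, rng):
        star = parse_newick("(A:1,B:1,C:1,D:1,E:1,F:1);")
        X = pd.DataFrame(rng.normal(size=(6, 3)), index=star.tip_labels,
                         columns=list("xyz"))
        res = phylo_pca(X, star)
        Z = X.to_numpy() - X.to_numpy().mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(np.cov(Z.T)))[::-1]
        assert np.allclose(res.eigenvalues, evals, atol=1e-10)

    def test_reconstruction_full_rank(self, yule_tree_64, rng):
        X = self._traits(yule_tree_64, rng, p=3)
        res = phylo_pca(X, yule_tree_64)
        Z = res.scores.to_numpy() @ res.loadings.to_numpy().T
        C = phylo_vcv(yule_tree_64).C
        Cinv = np.linalg.inv(C)
        one = np.ones(len(X))
        a = (one @ Cinv @ X.to_numpy()) / (one @ Cinv @ one)
        assert np.allclose(Z, X.to_numpy() - a, atol=1e-8)

    def test_contributions_sum_to_one(self, yule_tree_64, rng):
        X = self._traits(yule_tree_64, rng)
        res = phylo_pca(X, yule_tree_64)
        assert np.allclose(res.contributions.sum(axis=0), 1.0)


class TestComputeSignal:
    def test_columns_and_degenerate_skip(self, yule_tree_64, caplog):
        rng = np.random.default_rng(0)
        traits = pd.DataFrame(
            {
                "bm": sim_traits(yule_tree_64, "brownian", 1.0, rng),
                "flat": np.ones(64),
            },
            index=yule_tree_64.tip_labels,
        )
        with caplog.at_level("WARNING", logger="mgc_ecoscreen"):
            out = compute_signal(traits, yule_tree_64, n_perm=49, seed=1)
        assert list(out.columns) == ["K", "p_K", "lambda_hat", "p_lambda"]
        assert list(out.index) == ["bm"]
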
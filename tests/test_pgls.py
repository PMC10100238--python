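"""PGLS estimation: closed forms, oracles, and the lambda profile."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from avibrain.pgls import (
    DesignMatrix,
    PGLSError,
    SingularityError,
    aic,
    fit_pgls,
    gls_solve,
    lambda_transform,
)
from avibrain.simulate import simulate_bm, simulate_tree
from avibrain.treeio import Phylogeny, vcv

from _oracles import dense_gls
from conftest import random_tree_newick


class TestLambdaTransform:
    V = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])

    def test_identity_at_one(self):
        assert np.array_equal(lambda_transform(self.V, 1.0), self.V)

    def test_star_limit_at_zero(self):
        assert np.array_equal(lambda_transform(self.V, 0.0), np.diag([2.0, 2.0, 2.0]))

    def test_half(self):
        out = lambda_transform(self.V, 0.5)
        assert np.allclose(out, [[2, 0.5, 0], [0.5, 2, 0], [0, 0, 2]])

    @pytest.mark.parametrize("lam", [-0.1, 1.1])
    def test_domain_error(self, lam):
        with pytest.raises(PGLSError):
            lambda_transform(self.V, lam)

    @given(st.floats(0.0, 1.0))
    def test_diagonal_always_unchanged(self, lam):
        out = lambda_transform(self.V, lam)
        assert np.array_equal(np.diag(out), np.diag(self.V))


class TestGlsSolve:
    def test_intercept_only_identity_cov(self):
        X = np.ones((3, 1))
        beta, se, sigma2, ll = gls_solve(X, np.array([1.0, 2.0, 3.0]), np.eye(3))
        assert beta[0] == pytest.approx(2.0)
        assert sigma2 == pytest.approx(2.0 / 3.0)

    def test_identity_cov_reduces_to_ols(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        y = rng.normal(size=30)
        beta, se, *_ = gls_solve(X, y, np.eye(30))
        import statsmodels.api as sm

        ols = sm.OLS(y, X).fit()
        assert np.allclose(beta, ols.params, atol=1e-10)
        assert np.allclose(se, ols.bse, atol=1e-10)

    def test_beta_invariant_to_cov_scale(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = rng.normal(size=20)
        b1, *_ = gls_solve(X, y, np.eye(20))
        b2, *_ = gls_solve(X, y, 7.3 * np.eye(20))
        assert np.allclose(b1, b2, atol=1e-10)

    def test_cholesky_matches_dense_inverse_route(self, rng):
        newick = random_tree_newick(50, rng)
        phy = Phylogeny.from_newick(newick)
        V = lambda_transform(vcv(phy).V, 0.7)
        X = np.column_stack([np.ones(50), rng.normal(size=(50, 2))])
        y = rng.normal(size=50)
        beta, se, sigma2, ll = gls_solve(X, y, V)
        ob, ose, os2, oll = dense_gls(X, y, V)
        assert np.allclose(beta, ob, atol=1e-8)
        assert np.allclose(se, ose, atol=1e-8)
        assert ll == pytest.approx(oll, abs=1e-8)

    def test_singular_design_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(SingularityError):
            gls_solve(X, np.zeros(4), np.eye(4))


class TestFitPgls:
    def test_lambda_zero_on_star_tree_is_ols(self, rng):
        phy = Phylogeny.from_newick("(" + ",".join(f"t{i}:1" for i in range(25)) + ");")
        X = np.column_stack([np.ones(25), rng.normal(size=25)])
        y = rng.normal(size=25)
        dm = DesignMatrix(X, ["intercept", "x"], list(phy.tips))
        fit = fit_pgls(dm, y, phy, lam=0.0)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta, ols, atol=1e-10)
        assert fit.lambda_fixed and fit.k == 3  # 2 betas + sigma2

    def test_ml_loglik_matches_dense_oracle_at_fixed_lambda(self, rng):
        tree = simulate_tree(40, seed=5)
        cov = vcv(tree)
        X = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
        y = np.asarray(simulate_bm(cov, 1.0, 0.7, seed=8))
        dm = DesignMatrix(X, ["intercept", "a", "b"], list(cov.taxa))
        fit = fit_pgls(dm, y, cov, lam=0.7)
        Vl = lambda_transform(cov.V, 0.7)
        ob, ose, os2, oll = dense_gls(X, y, Vl)
        assert np.allclose(fit.beta, ob, atol=1e-8)
        assert np.allclose(fit.se, ose, atol=1e-8)
        assert fit.loglik == pytest.approx(oll, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_profile_optimum_beats_fine_grid(self, seed):
        tree = simulate_tree(60, seed=seed)
        cov = vcv(tree)
        y = np.asarray(simulate_bm(cov, 1.0, 0.5, seed=100 + seed))
        dm = DesignMatrix(np.ones((60, 1)), ["intercept"], list(cov.taxa))
        fit = fit_pgls(dm, y, cov, lam="ml")
        grid_lls = [fit_pgls(dm, y, cov, lam=g).loglik for g in np.linspace(0, 1, 101)]
        assert fit.loglik >= max(grid_lls) - 1e-7

    def test_noise_column_never_decreases_loglik(self, rng, cov200):
        y = np.asarray(simulate_bm(cov200, 1.0, 0.8, seed=9))
        taxa = list(cov200.taxa)
        dm0 = DesignMatrix(np.ones((200, 1)), ["intercept"], taxa)
        base = fit_pgls(dm0, y, cov200)
        for _ in range(3):
            X = np.column_stack([np.ones(200), rng.normal(size=200)])
            dm = DesignMatrix(X, ["intercept", "noise"], taxa)
            full = fit_pgls(dm, y, cov200)
            assert full.loglik >= base.loglik - 1e-8

    def test_lambda_recovery_smoke(self, cov200):
        high = sum(
            fit_pgls(
                DesignMatrix(np.ones((200, 1)), ["intercept"], list(cov200.taxa)),
                np.asarray(simulate_bm(cov200, 1.0, 1.0, seed=s)),
                cov200,
            ).lam
            >= 0.9
            for s in range(10)
        )
        assert high >= 9

    def test_permuted_tips_lose_signal(self, cov200, rng):
        low = 0
        dm = DesignMatrix(np.ones((200, 1)), ["intercept"], list(cov200.taxa))
        for s in range(10):
            y = np.asarray(simulate_bm(cov200, 1.0, 1.0, seed=50 + s))
            low += fit_pgls(dm, rng.permutation(y), cov200).lam <= 0.1
        assert low >= 9

    def test_non_finite_response_rejected(self, cov200):
        dm = DesignMatrix(np.ones((200, 1)), ["intercept"], list(cov200.taxa))
        y = np.zeros(200)
        y[0] = np.nan
        with pytest.raises(PGLSError, match="non-finite"):
            fit_pgls(dm, y, cov200)


class TestAic:
    def test_direct_formula(self):
        tree = simulate_tree(20, seed=2)
        cov = vcv(tree)
        y = np.asarray(simulate_bm(cov, 1.0, 1.0, seed=3))
        dm = DesignMatrix(np.ones((20, 1)), ["intercept"], list(cov.taxa))
        fit = fit_pgls(dm, y, cov)
        assert aic(fit) == pytest.approx(-2 * fit.loglik + 2 * fit.k)
        # k: 1 beta + sigma2 + lambda when lambda is estimated
        assert fit.k == 3

    def test_equal_loglik_k_penalty(self):
        # same fit re-labelled with k differing by 1 -> AIC differs by 2
        tree = simulate_tree(20, seed=4)
        cov = vcv(tree)
        y = np.asarray(simulate_bm(cov, 1.0, 1.0, seed=5))
        dm = DesignMatrix(np.ones((20, 1)), ["intercept"], list(cov.taxa))
        ml = fit_pgls(dm, y, cov, lam="ml")
        fixed = fit_pgls(dm, y, cov, lam=ml.lam)
        assert fixed.loglik == pytest.approx(ml.loglik, abs=1e-9)
        assert ml.aic - fixed.aic == pytest.approx(2.0)

    def test_nested_ml_loglik_monotone(self, rng, cov200):
        y = np.asarray(simulate_bm(cov200, 1.0, 0.6, seed=6))
        taxa = list(cov200.taxa)
        X = np.column_stack([np.ones(200), rng.normal(size=(200, 2))])
        reduced = fit_pgls(DesignMatrix(X[:, :2], ["intercept", "a"], taxa), y, cov200)
        full = fit_pgls(DesignMatrix(X, ["intercept", "a", "b"], taxa), y, cov200)
        assert full.loglik >= reduced.loglik - 1e-8
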
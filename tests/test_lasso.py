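"""Constrained-LASSO solver oracles and lambda-path behaviour."""

import numpy as np
import pytest

from dysreg.errors import InputError
from dysreg.lasso import (
    PathParams,
    RegressionDesign,
    build_design,
    draw_lambdas,
    fit_constrained_lasso,
    lambda_max,
    lambda_path,
)


def _design(rng, n=80, k=6, beta=None, noise=0.5, gene="gene"):
    X = rng.normal(size=(n, k + 2))
    if beta is None:
        beta = np.zeros(k + 2)
    y = 1.0 + X @ beta + (rng.normal(0, noise, n) if noise else 0.0)
    return RegressionDesign(
        gene=gene, y=y, x_cna=X[:, 0], x_dm=X[:, 1], tf_matrix=X[:, 2:],
        tf_names=[f"T{i}" for i in range(k)],
    )


def _ols(X, y):
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef


class TestSolverOracles:
    def test_lambda_above_lambda_max_returns_forced_covariate_ols(self, rng):
        d = _design(rng, beta=np.array([0.5, -0.5, 0.4, 0, 0, 0, 0, 0]))
        lmax = lambda_max(d)
        sol = fit_constrained_lasso(d, lmax * 1.001)
        assert sol.beta_tf == {}
        ref = _ols(np.column_stack([d.x_cna, d.x_dm]), d.y)
        assert sol.intercept == pytest.approx(ref[0], abs=1e-6)
        assert sol.beta_cna == pytest.approx(ref[1], abs=1e-6)
        assert sol.beta_dm == pytest.approx(ref[2], abs=1e-6)

    def test_zero_lambda_equals_full_ols(self, rng):
        d = _design(rng, n=60, k=5,
                    beta=np.array([0.5, -0.3, 0.4, -0.2, 0.1, 0.3, 0.0]))
        sol = fit_constrained_lasso(d, 0.0)
        ref = _ols(d.X, d.y)
        got = [sol.intercept, sol.beta_cna, sol.beta_dm] + [
            sol.beta_tf.get(t, 0.0) for t in d.tf_names
        ]
        np.testing.assert_allclose(got, ref, atol=1e-6)

    def test_soft_threshold_closed_form_on_orthogonal_column(self, rng):
        """One penalised column orthogonal to the forced block: the solution
        is sign(z) * max(|z| - lambda, 0) with z the column/response
        covariance."""
        n = 200
        U = rng.normal(size=(n, 2))
        x = rng.normal(size=n)
        # orthogonalise against (1, U) and scale to ||x||^2 / n = 1
        A = np.column_stack([np.ones(n), U])
        x = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
        x = x / np.sqrt(np.mean(x**2))
        y = rng.normal(size=n)
        y = y - y.mean()
        z = float(x @ y / n)
        d = RegressionDesign(
            gene="g", y=y, x_cna=U[:, 0], x_dm=U[:, 1],
            tf_matrix=x[:, None], tf_names=["T0"],
        )
        for lam in np.linspace(0.0, abs(z) * 1.2, 9):
            sol = fit_constrained_lasso(d, lam)
            expected = np.sign(z) * max(abs(z) - lam, 0.0)
            assert sol.beta_tf.get("T0", 0.0) == pytest.approx(expected, abs=1e-6)

    def test_matches_frozen_glmnet_reference(self):
        """Frozen reference solution computed with R glmnet 4.1
        (penalty.factor = c(0,0,1,...,1), standardize = TRUE, thresh = 1e-14,
        lambda rescaled by sum(penalty.factor)/nvars)."""
        rng = np.random.default_rng(5)
        n, k = 80, 6
        X = rng.normal(size=(n, k + 2))
        X = (X - X.mean(0)) / X.std(0)
        beta = np.array([0.8, -0.5, 0.6, 0.0, -0.4, 0.0, 0.3, 0.0])
        y = 1.2 + X @ beta + rng.normal(0, 0.5, n)
        d = RegressionDesign(
            gene="g", y=y, x_cna=X[:, 0], x_dm=X[:, 1], tf_matrix=X[:, 2:],
            tf_names=[f"T{i}" for i in range(k)],
        )
        sol = fit_constrained_lasso(d, 0.08)
        assert sol.intercept == pytest.approx(1.164265, abs=1e-5)
        assert sol.beta_cna == pytest.approx(0.775481, abs=1e-5)
        assert sol.beta_dm == pytest.approx(-0.482937, abs=1e-5)
        expected_tf = {"T0": 0.433212, "T2": -0.289728, "T4": 0.120626}
        assert set(sol.beta_tf) == set(expected_tf)
        for t, v in expected_tf.items():
            assert sol.beta_tf[t] == pytest.approx(v, abs=1e-5)

    def test_forced_covariates_survive_any_lambda(self, rng):
        d = _design(rng, beta=np.array([1.0, -1.0, 0, 0, 0, 0, 0, 0]))
        for lam in (0.01, 1.0, 100.0):
            sol = fit_constrained_lasso(d, lam)
            assert sol.beta_cna != 0.0
            assert sol.beta_dm != 0.0

    def test_support_empties_just_above_lambda_max(self, rng):
        d = _design(rng, beta=np.array([0.3, 0.1, 0.5, -0.5, 0, 0, 0, 0]))
        lmax = lambda_max(d)
        assert fit_constrained_lasso(d, lmax * (1 + 1e-9)).beta_tf == {}
        # and is nonempty just below
        assert fit_constrained_lasso(d, lmax * 0.95).beta_tf != {}

    def test_invalid_inputs_rejected(self, rng):
        d = _design(rng)
        with pytest.raises(InputError):
            fit_constrained_lasso(d, -0.1)
        bad = _design(rng)
        bad.y[0] = np.nan
        with pytest.raises(InputError):
            RegressionDesign(
                gene="g", y=bad.y, x_cna=bad.x_cna, x_dm=bad.x_dm,
                tf_matrix=bad.tf_matrix, tf_names=bad.tf_names,
            )

    def test_response_gene_not_allowed_in_tf_block(self, rng):
        d = _design(rng)
        with pytest.raises(InputError):
            RegressionDesign(
                gene="T0", y=d.y, x_cna=d.x_cna, x_dm=d.x_dm,
                tf_matrix=d.tf_matrix, tf_names=d.tf_names,
            )


class TestLambdaDraws:
    def test_fixed_seed_gives_identical_draws(self, rng):
        d = _design(rng, beta=np.array([0.5, -0.5, 0.6, 0, 0, 0, 0, 0]))
        p = PathParams(folds=5, n_points=40)
        l1 = draw_lambdas(d, repeats=5, seed=3, params=p)
        l2 = draw_lambdas(d, repeats=5, seed=3, params=p)
        np.testing.assert_array_equal(l1, l2)

    def test_single_repeat_within_path_bounds(self, rng):
        d = _design(rng, beta=np.array([0.5, -0.5, 0.6, 0, 0, 0, 0, 0]))
        p = PathParams(folds=5, n_points=40)
        lams = draw_lambdas(d, repeats=1, seed=0, params=p)
        assert lams.shape == (1,)
        assert 0 < lams[0] <= lambda_max(d) + 1e-12

    def test_noiseless_signal_retains_true_tfs_at_every_drawn_lambda(self, rng):
        beta = np.zeros(12 + 2)
        beta[:2] = [0.4, -0.4]
        beta[2:5] = [0.8, -0.7, 0.9]
        d = _design(rng, n=200, k=12, beta=beta, noise=0.0)
        p = PathParams(folds=5, n_points=60)
        lams = draw_lambdas(d, repeats=20, seed=4, params=p)
        for lam in np.unique(lams):
            sol = fit_constrained_lasso(d, lam)
            assert {"T0", "T1", "T2"} <= set(sol.beta_tf)

    def test_too_few_samples_for_folds_rejected(self, rng):
        d = _design(rng, n=5)
        with pytest.raises(InputError):
            draw_lambdas(d, repeats=1, seed=0, params=PathParams(folds=10))


def test_lambda_path_geometry(rng):
    d = _design(rng, beta=np.array([0.5, -0.5, 0.6, 0, 0, 0, 0, 0]))
    path = lambda_path(d, ratio=1e-2, n_points=10)
    assert path[0] == pytest.approx(lambda_max(d))
    assert path[-1] == pytest.approx(path[0] * 1e-2)
    ratios = path[1:] / path[:-1]
    np.testing.assert_allclose(ratios, ratios[0])


def test_build_design_excludes_self_loop(small_cohort):
    bundle, _ = small_cohort
    gene = bundle.panel_genes[0]
    d = build_design(bundle, gene)
    assert gene not in d.tf_names
    assert d.tf_matrix.shape == (len(bundle.tumour_samples), len(d.tf_names))
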
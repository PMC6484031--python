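"""Regression families: null, Bayesian Lasso, RKHS, tree ensembles, classifier."""

import numpy as np
import pandas as pd
import pytest

from biomepred.predictors import (
    BLHyper,
    EnsembleParams,
    RKHSHyper,
    build_fixed_design,
    classify_timepoint,
    fit_bayesian_lasso,
    fit_forest,
    fit_gbm,
    fit_null,
    fit_rkhs,
    select_lambda,
)
from biomepred.synthetic_cohort import CohortConfig, generate_design, generate_microbiome


def _xw(rng, n, p):
    X = pd.DataFrame(
        {"intercept": np.ones(n), "x1": rng.normal(size=n)},
        index=[f"a{i}" for i in range(n)],
    )
    W = pd.DataFrame(
        rng.normal(size=(n, p)), index=X.index, columns=[f"w{j}" for j in range(p)]
    )
    return X, W


class TestFixedDesign:
    def test_full_rank_with_reference_coding(self):
        design = generate_design(CohortConfig(n_sires=4, n_replicates=3, seed=0))
        X = build_fixed_design(design)
        Xm = X.to_numpy(dtype=float)
        assert np.linalg.matrix_rank(Xm) == Xm.shape[1]
        # intercept + (2-1) sex + (3-1) replicate + (4-1) sire + covariate
        assert Xm.shape[1] == 1 + 1 + 2 + 3 + 1

    def test_predictions_invariant_to_factor_coding(self, rng):
        design = generate_design(CohortConfig(n_sires=3, n_replicates=2, seed=1))
        y = rng.normal(size=len(design))
        X_ref = build_fixed_design(design, drop_first=True)
        X_ovr = build_fixed_design(design, drop_first=False)  # aliased, gets dropped
        with pytest.warns(UserWarning, match="aliased"):
            fit_o = fit_null(y, X_ovr)
        fit_r = fit_null(y, X_ref)
        assert np.allclose(fit_r.predict(X_ref), fit_o.predict(X_ovr), atol=1e-8)


class TestFitNull:
    def test_noiseless_linear_data_fit_exactly(self, rng):
        X, _ = _xw(rng, 40, 1)
        y = 2.0 + 3.0 * X["x1"].to_numpy()
        fit = fit_null(y, X)
        assert np.allclose(fit.predict(X), y, atol=1e-10)

    def test_intercept_only_predicts_training_mean(self, rng):
        y = rng.normal(size=25)
        X = pd.DataFrame({"intercept": np.ones(25)})
        fit = fit_null(y, X)
        assert np.allclose(fit.predict(X), y.mean())

    def test_posterior_mean_equals_normal_equations_solve(self, rng):
        n, p = 50, 5
        Xm = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        X = pd.DataFrame(Xm, columns=[f"c{i}" for i in range(p)])
        y = Xm @ rng.normal(size=p) + rng.normal(0, 0.5, n)
        fit = fit_null(y, X)
        beta = np.linalg.solve(Xm.T @ Xm, Xm.T @ y)
        assert np.allclose(fit.coef.to_numpy(), beta, atol=1e-10)


class TestBayesianLasso:
    def test_residual_prior_scale_formula(self):
        # Var(y)=1, R2=0.6, df=5 -> S_e = 1 * 0.4 * 7 = 2.8
        assert BLHyper(df_e=5, R2_e=0.6).residual_scale(1.0) == pytest.approx(2.8)

    def test_conditional_posterior_matches_ridge_closed_form(self, rng):
        n, p = 12, 2
        X, W = _xw(rng, n, p)
        X = X[["intercept"]]
        y = W.to_numpy() @ np.array([1.0, -0.5]) + rng.normal(0, 0.5, n)
        sigma2, tau2 = 0.25, 4.0
        hyper = BLHyper(lam=10, iterations=8000, burn_in=1000, thin=2, seed=1)
        fit = fit_bayesian_lasso(y, X, W, hyper, fixed_sigma2=sigma2, fixed_tau2=tau2)
        # joint conjugate solve: flat intercept + ridge prior 1/tau2 on o
        Xm, Wm = X.to_numpy(), W.to_numpy()
        A = np.block(
            [
                [Xm.T @ Xm, Xm.T @ Wm],
                [Wm.T @ Xm, Wm.T @ Wm + np.eye(p) / tau2],
            ]
        )
        sol = np.linalg.solve(A, np.concatenate([Xm.T @ y, Wm.T @ y]))
        mc_se = fit.o_sd.to_numpy() / np.sqrt(fit.n_kept / 10)  # conservative ESS
        assert (np.abs(fit.o_mean.to_numpy() - sol[1:]) < 3 * mc_se).all()

    def test_huge_lambda_collapses_to_null_model(self, rng):
        n, p = 60, 10
        X, W = _xw(rng, n, p)
        y = 1.0 + 0.5 * X["x1"].to_numpy() + rng.normal(0, 0.3, n)
        hyper = BLHyper(lam=1e6, iterations=2000, burn_in=500, thin=2, seed=2)
        fit = fit_bayesian_lasso(y, X, W, hyper)
        assert np.abs(fit.o_mean).max() < 1e-4
        null = fit_null(y, X)
        assert np.allclose(fit.predict(X, W), null.predict(X), atol=0.05)

    def test_posterior_means_stable_across_seeds(self, rng):
        n, p = 80, 8
        X, W = _xw(rng, n, p)
        o_true = np.zeros(p)
        o_true[:2] = [0.8, -0.8]
        y = W.to_numpy() @ o_true + rng.normal(0, 0.5, n)
        fits = [
            fit_bayesian_lasso(
                y, X, W, BLHyper(lam=5, iterations=4000, burn_in=1000, thin=2, seed=s)
            )
            for s in (1, 2)
        ]
        se = np.sqrt(
            fits[0].o_sd.to_numpy() ** 2 / (fits[0].n_kept / 10)
            + fits[1].o_sd.to_numpy() ** 2 / (fits[1].n_kept / 10)
        )
        assert (
            np.abs(fits[0].o_mean.to_numpy() - fits[1].o_mean.to_numpy()) < 3 * se
        ).all()

    def test_non_finite_input_rejected(self, rng):
        X, W = _xw(rng, 10, 2)
        y = np.full(10, np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            fit_bayesian_lasso(
                y, X, W, BLHyper(lam=1, iterations=10, burn_in=1, thin=1)
            )


class TestSelectLambda:
    def test_single_value_grid_returned_directly(self, rng):
        X, W = _xw(rng, 10, 2)
        assert select_lambda(rng.normal(size=10), X, W, grid=[7.0]) == 7.0

    def test_empty_grid_rejected(self, rng):
        X, W = _xw(rng, 10, 2)
        with pytest.raises(ValueError, match="empty"):
            select_lambda(rng.normal(size=10), X, W, grid=[])

    def test_noise_prefers_stronger_shrinkage_than_signal(self):
        # paired simulation: pure-noise vs strong dense signal
        grid = (1.0, 200.0)
        hyper = BLHyper(iterations=600, burn_in=200, thin=2, seed=0)
        noise_picks, signal_picks = [], []
        for rep in range(5):
            r = np.random.default_rng(100 + rep)
            X, W = _xw(r, 60, 12)
            y_noise = r.normal(size=60)
            y_signal = W.to_numpy() @ r.normal(0, 0.5, 12) + r.normal(0, 0.3, 60)
            noise_picks.append(
                select_lambda(y_noise, X, W, grid=grid, hyper=hyper, seed=rep)
            )
            signal_picks.append(
                select_lambda(y_signal, X, W, grid=grid, hyper=hyper, seed=rep)
            )
        assert np.mean(noise_picks) > np.mean(signal_picks)
        assert np.mean([p == 200.0 for p in noise_picks]) >= 0.8
        assert all(p == 1.0 for p in signal_picks)


class TestRKHS:
    def test_identity_kernel_reduces_to_null_model(self, rng):
        n = 40
        ids = [f"a{i}" for i in range(n)]
        X = pd.DataFrame(
            {"intercept": np.ones(n), "x1": rng.normal(size=n)}, index=ids
        )
        y = 1.0 + X["x1"].to_numpy() + rng.normal(0, 0.4, n)
        M = pd.DataFrame(np.eye(n), index=ids, columns=ids)
        hyper = RKHSHyper(iterations=3000, burn_in=500, thin=2, seed=3)
        fit = fit_rkhs(y[:30], X, M, hyper, train_ids=ids[:30], test_ids=ids[30:])
        null = fit_null(y[:30], X.iloc[:30])
        # off-diagonal zeros share no information: kriging mean is 0
        assert np.allclose(
            fit.predictions.to_numpy(), null.predict(X.iloc[30:]), atol=0.08
        )

    def test_posterior_mean_matches_henderson_mme_at_fixed_variances(self, rng):
        n = 40
        ids = [f"a{i}" for i in range(n)]
        dist = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        K = np.exp(-0.5 * (dist / 5.0) ** 2) + 1e-6 * np.eye(n)
        M = pd.DataFrame(K, index=ids, columns=ids)
        X = pd.DataFrame(
            {"intercept": np.ones(n), "x": rng.normal(size=n)}, index=ids
        )
        u = np.linalg.cholesky(K) @ rng.normal(size=n)
        y = X.to_numpy() @ np.array([1.0, 0.5]) + u + rng.normal(0, 0.5, n)
        s2u, s2e = 1.0, 0.25
        fit = fit_rkhs(
            y,
            X,
            M,
            RKHSHyper(iterations=10000, burn_in=1000, thin=2, seed=4),
            fixed_sigma2_u=s2u,
            fixed_sigma2_e=s2e,
        )
        Xm = X.to_numpy()
        lam = s2e / s2u
        A = np.block(
            [[Xm.T @ Xm, Xm.T], [Xm, np.eye(n) + lam * np.linalg.inv(K)]]
        )
        sol = np.linalg.solve(A, np.concatenate([Xm.T @ y, y]))
        assert np.abs(fit.u_train.to_numpy() - sol[2:]).max() < 0.05
        assert np.allclose(fit.b_mean.to_numpy(), sol[:2], atol=0.05)

    def test_variance_ratio_recovery(self, rng):
        # u ~ N(0, 2 M), sigma_e^2 = 1 -> ratio 2/3
        n = 400
        ids = [f"a{i}" for i in range(n)]
        Z = rng.normal(size=(n, 30)) / np.sqrt(30)
        K = 0.2 * np.eye(n) + 0.8 * (Z @ Z.T)
        d = np.sqrt(np.diag(K))
        K = K / np.outer(d, d)
        M = pd.DataFrame(K, index=ids, columns=ids)
        X = pd.DataFrame({"intercept": np.ones(n)}, index=ids)
        u = np.linalg.cholesky(K + 1e-10 * np.eye(n)) @ rng.normal(size=n) * np.sqrt(2)
        y = 1.0 + u + rng.normal(0, 1.0, n)
        fit = fit_rkhs(
            y, X, M, RKHSHyper(iterations=4000, burn_in=1000, thin=2, seed=5)
        )
        ratio = fit.sigma2_u_mean / (fit.sigma2_u_mean + fit.sigma2_e_mean)
        assert abs(ratio - 2 / 3) < 0.1


class TestEnsembles:
    def test_forest_feature_subset_is_floor_sqrt(self):
        assert int(np.sqrt(1755)) == 41  # floor(sqrt(p)) rule at the study scale
        params = EnsembleParams(n_trees=5, seed=0)
        rng = np.random.default_rng(0)
        feats = pd.DataFrame(rng.normal(size=(30, 10)))
        fit = fit_forest(rng.normal(size=30), feats, params)
        assert fit.model.max_features == "sqrt"
        assert fit.model.estimators_[0].max_features_ == 3  # floor(sqrt(10))

    def test_constant_target_predicted_exactly(self, rng):
        feats = pd.DataFrame(rng.normal(size=(25, 4)))
        y = np.full(25, 3.7)
        fit = fit_forest(y, feats, EnsembleParams(n_trees=10, seed=0))
        assert np.allclose(fit.predict(feats), 3.7)

    def test_forest_learns_noiseless_single_feature(self, rng):
        n = 500
        feats = pd.DataFrame({"x": rng.uniform(-2, 2, n)})
        y = np.sin(2 * feats["x"].to_numpy())
        fit = fit_forest(y, feats, EnsembleParams(n_trees=100, seed=1))
        pred = fit.predict(feats)
        r2 = 1 - np.mean((y - pred) ** 2) / np.var(y)
        assert r2 > 0.95

    @pytest.mark.parametrize("kwargs", [dict(n_trees=0), dict(gbm_shrinkage=0.0)])
    def test_degenerate_gbm_predicts_training_mean(self, rng, kwargs):
        feats = pd.DataFrame(rng.normal(size=(30, 3)))
        y = rng.normal(2.0, 1.0, 30)
        fit = fit_gbm(y, feats, EnsembleParams(seed=0, **kwargs))
        assert np.allclose(fit.predict(feats), y.mean())

    def test_gbm_staged_training_loss_non_increasing(self, rng):
        n = 200
        feats = pd.DataFrame(rng.normal(size=(n, 5)))
        y = feats.iloc[:, 0].to_numpy() + 0.3 * rng.normal(size=n)
        fit = fit_gbm(
            y, feats, EnsembleParams(n_trees=150, gbm_bag_fraction=1.0, seed=2)
        )
        losses = fit.staged_train_loss(feats, y)
        assert len(losses) == 150
        assert (np.diff(losses) <= 1e-12).all()

    def test_no_features_rejected(self, rng):
        with pytest.raises(ValueError, match="feature"):
            fit_forest(rng.normal(size=5), pd.DataFrame(index=range(5)), EnsembleParams())

    def test_deterministic_given_seed(self, rng):
        feats = pd.DataFrame(rng.normal(size=(50, 6)))
        y = rng.normal(size=50)
        p1 = fit_forest(y, feats, EnsembleParams(n_trees=20, seed=9)).predict(feats)
        p2 = fit_forest(y, feats, EnsembleParams(n_trees=20, seed=9)).predict(feats)
        assert np.array_equal(p1, p2)


class TestClassifyTimepoint:
    @pytest.fixture(scope="class")
    @staticmethod
    def cohort():
        cfg = CohortConfig(n_sires=5, n_replicates=2, n_otus=60, depth=800, seed=13)
        design = generate_design(cfg)
        return cfg, design

    def test_separated_timepoints_classified_almost_perfectly(self, cohort):
        cfg, design = cohort
        tables = generate_microbiome(design, cfg, separation=1.5)
        cm = classify_timepoint(
            tables, n_folds=3, params=EnsembleParams(n_trees=80, seed=0), seed=0
        )
        assert (np.diag(cm.matrix) >= 0.95).all()

    def test_zero_separation_gives_chance_level_diagonal(self, cohort):
        cfg, design = cohort
        tables = generate_microbiome(design, cfg, separation=0.0)
        cm = classify_timepoint(
            tables, n_folds=3, params=EnsembleParams(n_trees=80, seed=0), seed=0
        )
        n_per_class = tables["wean"].n_samples
        se = np.sqrt((1 / 3) * (2 / 3) / n_per_class)
        assert (np.abs(np.diag(cm.matrix) - 1 / 3) < 4 * se).all()

    def test_rows_sum_to_one(self, cohort):
        cfg, design = cohort
        tables = generate_microbiome(design, cfg, separation=0.5)
        cm = classify_timepoint(
            tables, n_folds=3, params=EnsembleParams(n_trees=40, seed=1), seed=1
        )
        assert np.allclose(cm.matrix.sum(axis=1), 1.0, atol=1e-12)
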
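"""Penalized EM fitter: closed-form reductions, quadrature oracles,
parameter recovery on simulated ground truth, and CV behaviour."""

import numpy as np
import pandas as pd
import pytest
from sklearn.covariance import graphical_lasso

from zicopula import (
    CommunityModel,
    CommunityProfileModel,
    CopulaCorrelation,
    DepthModel,
    FeatureTable,
    FitConfig,
    FixtureSpec,
    cross_validate_lambda,
    estimate_pi,
    fit_depth,
    fit_em,
    initialize_params,
    make_template_table,
    normalize_counts,
    simulate,
)
from zicopula.fitting import _latent_second_moment, e_step, m_step


def _table(values, kind="counts"):
    values = np.asarray(values, dtype=float)
    return FeatureTable(
        feature_ids=[f"f{j}" for j in range(values.shape[0])],
        sample_ids=[f"s{i}" for i in range(values.shape[1])],
        values=values,
        kind=kind,
    )


class TestNormalizeCounts:
    def test_hand_normalization(self):
        t = normalize_counts(_table([[2], [3], [5]]))
        np.testing.assert_allclose(t.values[:, 0], [0.2, 0.3, 0.5])
        assert t.kind == "relabund"

    def test_degenerate_column(self):
        t = normalize_counts(_table([[10], [0], [0]]))
        np.testing.assert_allclose(t.values[:, 0], [1, 0, 0])

    def test_columns_sum_to_one(self, rng):
        vals = rng.integers(0, 50, size=(3, 4)) + 1
        t = normalize_counts(_table(vals))
        np.testing.assert_allclose(t.values.sum(axis=0), 1.0, atol=1e-12)

    def test_all_zero_sample_named(self):
        with pytest.raises(ValueError, match="s1"):
            normalize_counts(_table([[1, 0], [2, 0]]))


class TestEstimatePi:
    def test_counting(self, rng):
        pattern = rng.integers(0, 2, size=(5, 20)).astype(float)
        t = _table(pattern * 3)
        np.testing.assert_allclose(estimate_pi(t), (pattern == 0).mean(axis=1))

    def test_always_present_feature(self):
        t = _table(np.ones((2, 10)))
        assert estimate_pi(t)[0] == 0.0


class TestFitDepth:
    def test_constant_depths(self):
        d = fit_depth([10_000, 10_000, 10_000])
        assert d.mu_D == pytest.approx(np.log(10_000))
        assert d.sigma_D == 0.0

    def test_two_point_mle(self):
        d = fit_depth([np.e, np.e**3])
        assert d.mu_D == pytest.approx(2.0)
        assert d.sigma_D == pytest.approx(1.0)

    def test_monte_carlo_recovery(self, rng):
        depths = np.exp(rng.normal(9, 0.5, 1000))
        d = fit_depth(depths)
        assert d.mu_D == pytest.approx(9.0, abs=0.05)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fit_depth([100, 0])


class TestInitializeParams:
    def test_moment_recovery_independent_model(self):
        model = CommunityModel.from_arrays(
            [f"f{j}" for j in range(5)],
            [0.0] * 5,
            np.array([1.0, 0.5, 0.0, -0.5, -1.0]),
            [0.6] * 5,
            CopulaCorrelation.identity(5),
            DepthModel(10.0, 0.2),
        )
        sim = simulate(model, 2000, seed=4)
        init = initialize_params(sim.relabund_table())
        # centered mu is identified; relative-abundance scale shifts cancel
        assert np.abs(init.mu - model.mu).mean() < 0.1
        assert np.abs(init.sigma - model.sigma).mean() < 0.1

    def test_identical_features_have_unit_initial_correlation(self, rng):
        base = rng.lognormal(0, 1, size=200)
        other = rng.lognormal(0, 1, size=200)
        vals = np.vstack([base, base, other])
        t = normalize_counts(_table(vals, kind="absolute"))
        init = initialize_params(t)
        assert init.copula.corr[0, 1] > 0.85  # ridge shrinks the exact 1

    def test_independent_features_small_initial_correlation(self):
        """Independent features give small initial correlations. Note the
        sum-to-one closure induces a residual negative bias of order 1/p
        (at p=2 the two relative abundances are deterministic complements),
        so this is checked at p=5."""
        p = 5
        model = CommunityModel.from_arrays(
            [f"f{j}" for j in range(p)], [0.1] * p, [0.0] * p, [1.0] * p,
            CopulaCorrelation.identity(p), DepthModel(10.0, 0.2),
        )
        sim = simulate(model, 2000, seed=9)
        init = initialize_params(sim.relabund_table())
        off = init.copula.corr[~np.eye(p, dtype=bool)]
        assert np.abs(off).max() < 0.35
        assert np.abs(off).mean() < 0.2

    def test_rare_feature_rejected(self):
        vals = np.ones((3, 10))
        vals[0, 1:] = 0.0  # f0 present once
        with pytest.raises(ValueError, match="f0"):
            initialize_params(_table(vals))


class TestESteps:
    def test_univariate_reduction(self):
        """p=1: X is always 1, so the conditional of log A^Sigma is the
        marginal of log A_1 with mean mu_1."""
        model = CommunityModel.from_arrays(
            ["f0"], [0.0], [1.3], [0.7],
            CopulaCorrelation.identity(1), DepthModel(9.0, 0.2),
        )
        t = FeatureTable(["f0"], [f"s{i}" for i in range(5)],
                         np.ones((1, 5)), "relabund")
        state = e_step(t, model, FitConfig())
        np.testing.assert_allclose(state.exp_t, 1.3, atol=1e-8)
        np.testing.assert_allclose(state.exp_t2 - state.exp_t**2, 0.49, atol=1e-6)

    def test_moments_match_dense_grid_oracle(self):
        """pi=0, identity copula: compare against 10^4-node trapezoid
        integration of the exact conditional density of t."""
        p = 3
        mu = np.array([0.5, 0.0, -0.5])
        sigma = np.array([0.8, 1.0, 1.2])
        model = CommunityModel.from_arrays(
            [f"f{j}" for j in range(p)], [0.0] * p, mu, sigma,
            CopulaCorrelation.identity(p), DepthModel(9.0, 0.2),
        )
        x = np.array([[0.5], [0.3], [0.2]])
        t_table = FeatureTable([f"f{j}" for j in range(p)], ["s0"], x, "relabund")
        state = e_step(t_table, model, FitConfig())

        # oracle: with pi=0 and identity copula the conditional density of t
        # is proportional to prod_j phi((t + log x_j - mu_j)/sigma_j)
        grid = np.linspace(-10, 10, 10_000)
        logx = np.log(x[:, 0])
        logdens = sum(
            -0.5 * ((grid + lx - m) / s) ** 2 for lx, m, s in zip(logx, mu, sigma)
        )
        w = np.exp(logdens - logdens.max())
        w /= np.trapezoid(w, grid)
        et = np.trapezoid(w * grid, grid)
        et2 = np.trapezoid(w * grid**2, grid)
        assert state.exp_t[0] == pytest.approx(et, abs=1e-4)
        assert state.exp_t2[0] == pytest.approx(et2, abs=1e-4)

    def test_all_present_sample_has_deterministic_latent_scores(self, dense_small):
        sim = simulate(dense_small, 50, seed=3)
        full = np.flatnonzero((sim.relabund > 0).all(axis=1))[:3]
        t = FeatureTable(
            dense_small.feature_ids,
            [f"s{i}" for i in range(full.size)],
            sim.relabund[full].T,
            "relabund",
        )
        state = e_step(t, dense_small, FitConfig())
        assert np.all(state.gvar == 0)
        assert np.all(np.isfinite(state.gbar))


class TestMStep:
    @pytest.fixture()
    def estep_state(self, dense_small_table):
        model, table, _sim = dense_small_table
        rel = normalize_counts(table)
        init = initialize_params(rel)
        return init, rel, e_step(rel, init, FitConfig())

    def test_huge_penalty_gives_identity_correlation(self, estep_state):
        init, rel, state = estep_state
        new = m_step(state, rel, 1e6, init)
        off = new.copula.corr[~np.eye(new.p, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-8)

    def test_mu_recentered_exactly(self, estep_state):
        init, rel, state = estep_state
        new = m_step(state, rel, 0.1, init)
        assert abs(new.mu.sum()) < 1e-10

    def test_pi_never_updated(self, estep_state):
        init, rel, state = estep_state
        new = m_step(state, rel, 0.1, init)
        np.testing.assert_array_equal(new.pi, init.pi)

    def test_fully_present_reduction(self):
        """pi=0 everywhere: mu/sigma updates are the sample mean/SD of
        log x_ij + E[log A_i^Sigma]."""
        p, n = 4, 60
        rng = np.random.default_rng(12)
        vals = rng.lognormal(0, 1, size=(p, n))
        rel = normalize_counts(_table(vals, kind="absolute"))
        init = initialize_params(rel)
        state = e_step(rel, init, FitConfig())
        new = m_step(state, rel, 0.5, init)
        ela = np.log(rel.values) + state.exp_t[None, :]
        mu_expected = ela.mean(axis=1)
        mu_expected -= mu_expected.mean()
        np.testing.assert_allclose(new.mu, mu_expected, atol=1e-10)


class TestFitEM:
    def test_single_feature_rejected(self):
        with pytest.raises(ValueError):
            fit_em(_table(np.ones((1, 10))), 0.1)

    def test_objective_nonincreasing_in_exact_regime(self):
        """With no zero inflation the E-step is exact and the penalized
        objective decreases monotonically once EM proper is underway. The
        init -> first-iteration step is excluded: the moment-based start
        sits on the compositional non-identifiability ridge (a common
        log-normal factor traded against equicorrelation leaves f_X
        unchanged) and the first penalized M-step deliberately steps off
        it."""
        p = 6
        rng = np.random.default_rng(5)
        mu = rng.normal(0, 1, p)
        truth = CommunityModel.from_arrays(
            [f"f{j}" for j in range(p)], [0.0] * p, mu - mu.mean(),
            rng.uniform(0.5, 1.2, p), CopulaCorrelation.identity(p),
            DepthModel(9.0, 0.3),
        )
        sim = simulate(truth, 400, seed=2)
        res = fit_em(sim.relabund_table(), 0.05, FitConfig(max_iter=10))
        trace = np.asarray(res.objective_trace)[1:]
        rel_increase = np.diff(trace) / (np.abs(trace[:-1]) + 1)
        assert np.all(rel_increase <= 1e-4)

    def test_objective_stabilizes_with_zero_inflation(self, dense_small_table):
        """With zero inflation the truncated-conditional approximations make
        the surrogate objective only approximately monotone; it must still
        settle (successive changes shrink below the convergence tolerance)."""
        _model, table, _sim = dense_small_table
        res = fit_em(table, 0.05, FitConfig(max_iter=20))
        trace = np.asarray(res.objective_trace)
        assert res.converged
        last = abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1)
        assert last <= 1e-4

    def test_parameter_recovery(self):
        model, table, _sim = make_template_table(
            FixtureSpec(p=20, n=500, regime="gut_like", seed=21)
        )
        res = fit_em(table, 0.05, FitConfig(max_iter=25))
        assert np.abs(res.model.pi - model.pi).mean() < 0.05
        assert np.abs(res.model.mu - model.mu).mean() < 0.15
        assert np.abs(res.model.sigma - model.sigma).mean() < 0.15
        assert abs(res.model.mu.sum()) < 1e-8

    def test_refit_objective_not_worse_than_truth(self, dense_small_table):
        """The fitted parameters explain the fitter's own simulation at
        least as well as the generating parameters."""
        model, table, _sim = dense_small_table
        lam = 0.02
        res = fit_em(table, lam, FitConfig(max_iter=25))
        rel = normalize_counts(table)
        from zicopula.fitting import penalized_objective

        truth_obj = penalized_objective(e_step(rel, model, FitConfig()), model, lam)
        assert res.objective_trace[-1] <= truth_obj + 1e-6 * (abs(truth_obj) + 1)


class TestGraphicalLassoPath:
    def test_sparsity_nonincreasing_in_lambda(self, dense_small_table):
        model, table, _sim = dense_small_table
        rel = normalize_counts(table)
        init = initialize_params(rel)
        s = _latent_second_moment(e_step(rel, init, FitConfig()))
        s[np.diag_indices_from(s)] += 1e-6
        counts = []
        for lam in [0.01, 0.05, 0.2, 1.0]:
            _cov, prec = graphical_lasso(s, alpha=lam)
            off = prec[~np.eye(prec.shape[0], dtype=bool)]
            counts.append(int((np.abs(off) > 1e-8).sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestCrossValidation:
    def test_cv_table_and_determinism(self, dense_small_table):
        _model, table, _sim = dense_small_table
        config = FitConfig(lambda_grid=[0.02, 0.5], n_folds=3,
                           cv_max_iter=5, max_iter=8, seed=5)
        res1 = cross_validate_lambda(table, config)
        res2 = cross_validate_lambda(table, config)
        assert len(res1.cv_table) == 2
        pd.testing.assert_frame_equal(res1.cv_table, res2.cv_table)

    def test_correlated_truth_prefers_small_lambda(self):
        model, table, _sim = make_template_table(
            FixtureSpec(p=8, n=300, regime="dense_small", seed=31)
        )
        config = FitConfig(lambda_grid=[0.02, 1e6], n_folds=3,
                           cv_max_iter=8, max_iter=10, seed=2)
        res = cross_validate_lambda(table, config)
        tab = res.cv_table.set_index("lambda")["mean_heldout_loglik"]
        assert tab[0.02] >= tab[1e6]
        assert res.lambda_selected == 0.02

    def test_grid_of_one_short_circuits(self, dense_small_table):
        _model, table, _sim = dense_small_table
        res = cross_validate_lambda(
            table, FitConfig(lambda_grid=[0.1], max_iter=5)
        )
        assert res.cv_table is None
        assert res.lambda_selected == 0.1


class TestModelResultsSurface:
    def test_fit_and_summary(self, dense_small_table):
        _model, table, _sim = dense_small_table
        res = CommunityProfileModel(table, FitConfig(max_iter=8)).fit(lambda_=0.05)
        text = res.summary()
        assert "lambda" in text and "depth" in text
        assert res.params.shape == (table.p, 3)
        sim = res.simulate(20, seed=1)
        assert sim.counts.shape == (20, table.p)
        # depth fitted from the counts column totals
        assert res.community.depth.sigma_D > 0
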
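"""The MM conjugate-gradient optimizer: gradient, directions, fits."""

import numpy as np
import pytest
from scipy.optimize import approx_fprime, minimize

from iggaucs.data import SurvivalDataset
from iggaucs.gaucs import empirical_gaucs
from iggaucs.groups import GroupStructure, contiguous_groups
from iggaucs.optimizer import (
    OptimizerConfig,
    conjugate_direction,
    fit_iggaucs,
    surrogate_gradient,
)
from iggaucs.penalty import PenaltySpec, VariationalState, penalized_objective, surrogate_objective

from conftest import random_dataset


class TestConjugateDirection:
    def test_first_iteration_returns_gradient(self):
        g = np.array([1.0, -2.0])
        assert np.array_equal(conjugate_direction(g, None, None), g)

    def test_equal_gradients_give_zero_mixing(self):
        g = np.array([1.0, 2.0])
        d_prev = np.array([5.0, 5.0])
        assert np.allclose(conjugate_direction(g, g.copy(), d_prev), g)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        g, gp, dp = rng.normal(size=5), rng.normal(size=5), rng.normal(size=5)
        u = float((g - gp) @ g / (gp @ gp))
        expected = g + max(u, 0.0) * dp
        assert np.allclose(conjugate_direction(g, gp, dp), expected)
        expected_raw = g + u * dp
        assert np.allclose(conjugate_direction(g, gp, dp, clamp=False), expected_raw)

    def test_vanishing_previous_gradient_restarts(self):
        g = np.array([1.0, 1.0])
        assert np.array_equal(conjugate_direction(g, np.zeros(2), np.ones(2)), g)


class TestSurrogateGradient:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_finite_differences(self, seed):
        ds = random_dataset(n=20, m=6, seed=seed)
        st_ = contiguous_groups(6, 2)
        spec = PenaltySpec(p=0.4, lam=0.8)
        rng = np.random.default_rng(seed + 50)
        w = rng.normal(0, 1, size=6)
        vs = VariationalState(theta_norms=rng.uniform(0.5, 2, size=3), p=spec.p)

        def f(v):
            return surrogate_objective(ds, v, st_, vs, spec)

        g = surrogate_gradient(ds, w, st_, vs, spec)
        g_num = approx_fprime(w, f, 1e-6)
        assert np.allclose(g, g_num, rtol=1e-5, atol=1e-5)

    def test_zero_point_unpenalized_is_half_mean_difference(self):
        ds = random_dataset(n=12, m=3, seed=3)
        from iggaucs.gaucs import pair_differences

        st_ = contiguous_groups(3, 3)
        spec = PenaltySpec(p=0.5, lam=0.0)
        vs = VariationalState(theta_norms=np.ones(1), p=spec.p)
        D = pair_differences(ds)
        expected = 0.5 * D.mean(axis=0)
        assert np.allclose(surrogate_gradient(ds, np.zeros(3), st_, vs, spec), expected)

    def test_penalty_dominated_limit(self):
        ds = random_dataset(n=12, m=2, seed=4)
        st_ = contiguous_groups(2, 2)
        spec = PenaltySpec(p=1.0, lam=1e6)
        w = np.array([0.3, -0.4])
        vs = VariationalState.from_w(w, st_, spec.p)
        g = surrogate_gradient(ds, w, st_, vs, spec)
        expected = -2.0 * spec.lam * vs.eta[0] * w
        assert np.allclose(g, expected, rtol=1e-4)


class TestFitIggaucs:
    def test_unpenalized_separable_ranking_is_perfect(self):
        # one informative feature that perfectly reverses the time order
        t = np.arange(1.0, 13.0)
        X = np.column_stack([-t, np.zeros(12)])
        ds = SurvivalDataset(X=X, t=t, delta=np.ones(12, dtype=int))
        st_ = contiguous_groups(2, 1)
        fit = fit_iggaucs(ds, st_, PenaltySpec(p=0.5, lam=0.0), OptimizerConfig(seed=0))
        assert empirical_gaucs(ds, ds.X @ fit.w_hat) == 1.0

    def test_huge_lambda_empties_the_model(self, small_ds):
        st_ = contiguous_groups(4, 2)
        fit = fit_iggaucs(small_ds, st_, PenaltySpec(p=0.5, lam=1e4), OptimizerConfig(seed=0))
        assert fit.selected_groups == []
        assert np.array_equal(fit.w_hat, np.zeros(4))

    @pytest.mark.parametrize("seed", range(10))
    def test_objective_trace_monotone(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_dataset(n=25, m=6, seed=seed)
        st_ = contiguous_groups(6, 3)
        spec = PenaltySpec(p=float(rng.uniform(0.1, 1.0)), lam=float(rng.uniform(0, 0.5)))
        fit = fit_iggaucs(ds, st_, spec, OptimizerConfig(seed=seed, max_iter=150))
        diffs = np.diff(fit.objective_trace)
        assert np.all(diffs > -1e-8)

    def test_seeded_determinism(self, small_ds):
        st_ = contiguous_groups(4, 2)
        spec = PenaltySpec(p=0.3, lam=0.2)
        f1 = fit_iggaucs(small_ds, st_, spec, OptimizerConfig(seed=11))
        f2 = fit_iggaucs(small_ds, st_, spec, OptimizerConfig(seed=11))
        assert np.array_equal(f1.w_hat, f2.w_hat)
        assert f1.objective_trace == f2.objective_trace

    @pytest.mark.parametrize("seed", range(5))
    def test_convex_case_matches_generic_solver(self, seed):
        # p = 1, singleton groups, tiny m: penalized objective is concave,
        # so a derivative-free solver on the exact objective must agree
        ds = random_dataset(n=25, m=3, seed=seed + 30)
        st_ = contiguous_groups(3, 1)
        spec = PenaltySpec(p=1.0, lam=0.05)
        cfg = OptimizerConfig(seed=seed, eps=1e-9, max_iter=3000)
        fit = fit_iggaucs(ds, st_, spec, cfg)
        obj_mm = penalized_objective(ds, fit.w_hat, st_, spec)

        # multi-start: independent run from zero, polish run from ours
        oracle = -np.inf
        for x0 in (np.zeros(3), fit.w_hat):
            res = minimize(
                lambda w: -penalized_objective(ds, w, st_, spec),
                x0,
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
            )
            oracle = max(oracle, -res.fun)
        assert obj_mm == pytest.approx(oracle, abs=1e-4)

    def test_objective_nan_raises(self, small_ds):
        st_ = contiguous_groups(4, 2)
        bad = np.full(4, np.nan)
        with pytest.raises((FloatingPointError, ValueError)):
            fit_iggaucs(
                small_ds, st_, PenaltySpec(p=0.5, lam=0.1), OptimizerConfig(seed=0), w0=bad
            )

    def test_warm_start_freezes_zero_groups(self, small_ds):
        st_ = contiguous_groups(4, 2)
        w0 = np.array([0.5, -0.5, 0.0, 0.0])
        fit = fit_iggaucs(small_ds, st_, PenaltySpec(p=0.5, lam=0.1), OptimizerConfig(seed=0), w0=w0)
        assert np.array_equal(fit.w_hat[2:], np.zeros(2))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            OptimizerConfig(eps=0.0)
        with pytest.raises(ValueError):
            OptimizerConfig(freeze_tol=1e-3, prune_tol=1e-4)
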
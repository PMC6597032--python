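"""Weibull collapsing thresholds and simulation-based ML fitting."""

import numpy as np
import pytest

from valenceddm import boundaries as b


P_COLLAPSE = b.WeibullBoundaryParams(a=4.0, a_prime=0.5, lam=4.0, sigma2=1.0, x1=0.0)
P_FIXED = b.WeibullBoundaryParams(a=4.0, a_prime=4.0, lam=5.0, sigma2=1.0, x1=0.0)


class TestWeibullBoundary:
    def test_starts_at_initial_boundary(self):
        assert b.weibull_boundary(0.0, P_COLLAPSE) == pytest.approx(P_COLLAPSE.a)

    def test_fixed_reduction(self):
        t = np.arange(0, 50)
        np.testing.assert_allclose(b.weibull_boundary(t, P_FIXED), P_FIXED.a)

    def test_direct_substitution_at_scale(self):
        p = b.WeibullBoundaryParams(a=2.0, a_prime=0.0, lam=3.0, k=3.0, sigma2=1.0)
        assert b.weibull_boundary(3.0, p) == pytest.approx(2.0 * np.exp(-1.0), rel=1e-12)

    def test_monotone_nonincreasing_and_asymptote(self):
        t = np.linspace(0, 200, 2000)
        u = b.weibull_boundary(t, P_COLLAPSE)
        assert (np.diff(u) <= 1e-12).all()
        assert u[-1] == pytest.approx(P_COLLAPSE.a_prime, abs=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            b.WeibullBoundaryParams(a=2.0, a_prime=0.5, lam=-1.0)
        with pytest.raises(ValueError):
            b.WeibullBoundaryParams(a=2.0, a_prime=3.0, lam=1.0)
        with pytest.raises(ValueError):
            b.weibull_boundary(-1.0, P_COLLAPSE)


class TestAccumulator:
    def test_noise_free_ramp_is_deterministic(self):
        p = b.WeibullBoundaryParams(a=4.0, a_prime=4.0, lam=5.0, sigma2=0.0, x1=0.0)
        d = np.ones(30)
        resp, step, cens = b.simulate_accumulator(d, p, np.random.default_rng(0))
        assert (resp, step, cens) == (1, 4, False)  # ceil(a / |d|)
        p = b.WeibullBoundaryParams(a=4.5, a_prime=4.5, lam=5.0, sigma2=0.0, x1=0.0)
        resp, step, cens = b.simulate_accumulator(d, p, np.random.default_rng(0))
        assert step == 5

    def test_start_on_boundary_immediate_decision(self):
        u1 = b.weibull_boundary(1.0, P_COLLAPSE)
        p = b.WeibullBoundaryParams(a=4.0, a_prime=0.5, lam=4.0, sigma2=1.0, x1=u1)
        resp, step, cens = b.simulate_accumulator(np.ones(10), p, np.random.default_rng(1))
        assert (resp, step) == (1, 1)

    def test_collapse_shortens_decisions(self):
        rng1, rng2 = np.random.default_rng(2), np.random.default_rng(2)
        d = np.where(np.random.default_rng(3).random(60) < 0.6, 1.0, -1.0)
        col = b.WeibullBoundaryParams(a=6.0, a_prime=0.0, lam=2.0, sigma2=1.0)
        fix = b.WeibullBoundaryParams(a=6.0, a_prime=6.0, lam=2.0, sigma2=1.0)
        s_col, _, _ = b.simulate_decision_steps(d, col, 2000, rng1)
        s_fix, _, _ = b.simulate_decision_steps(d, fix, 2000, rng2)
        assert s_col.mean() < s_fix.mean()

    def test_stream_extended_when_exhausted(self):
        p = b.WeibullBoundaryParams(a=30.0, a_prime=30.0, lam=5.0, sigma2=0.0, x1=0.0)
        resp, step, cens = b.simulate_accumulator(np.ones(3), p, np.random.default_rng(4), max_steps=80, p_plus=1.0)
        assert step == 30 and not cens

    def test_censoring(self):
        p = b.WeibullBoundaryParams(a=500.0, a_prime=500.0, lam=5.0, sigma2=0.0, x1=0.0)
        _, _, cens = b.simulate_accumulator(np.ones(5), p, np.random.default_rng(5), max_steps=20)
        assert cens


class TestSimLikelihood:
    def test_perfect_match_gives_zero(self):
        p = b.WeibullBoundaryParams(a=4.0, a_prime=4.0, lam=5.0, sigma2=0.0, x1=0.0)
        trials = [(np.ones(10), 4), (np.ones(10), 4)]
        cfg = b.SimLikelihoodConfig(n_sim_per_trial=100)
        assert b.sim_likelihood(trials, p, cfg, np.random.default_rng(0)) == pytest.approx(0.0)

    def test_impossible_observation_hits_floor(self):
        p = b.WeibullBoundaryParams(a=4.0, a_prime=4.0, lam=5.0, sigma2=0.0, x1=0.0)
        trials = [(np.ones(10), 9)] * 3
        cfg = b.SimLikelihoodConfig(n_sim_per_trial=100)
        ll = b.sim_likelihood(trials, p, cfg, np.random.default_rng(0))
        assert ll == pytest.approx(3 * np.log(cfg.epsilon_floor))
        assert np.isfinite(ll)

    def test_trial_order_invariance(self):
        rng = np.random.default_rng(6)
        d = np.where(rng.random(30) < 0.6, 1.0, -1.0)
        trials = [(d, 3), (d, 7), (d, 5)]
        cfg = b.SimLikelihoodConfig(n_sim_per_trial=200)
        ll1 = b.sim_likelihood(trials, P_COLLAPSE, cfg, np.random.default_rng(7))
        ll2 = b.sim_likelihood(trials[::-1], P_COLLAPSE, cfg, np.random.default_rng(7))
        assert ll1 == ll2  # shared noise makes order invariance exact

    def test_likelihood_peaks_near_truth(self):
        rng = np.random.default_rng(8)
        trials = []
        for _ in range(30):
            d = np.where(rng.random(40) < 0.6, 1.0, -1.0)
            _, s, _ = b.simulate_accumulator(d, P_COLLAPSE, rng, max_steps=50)
            trials.append((d, s))
        cfg = b.SimLikelihoodConfig(n_sim_per_trial=400, max_steps=50)
        ll_true = b.sim_likelihood(trials, P_COLLAPSE, cfg, np.random.default_rng(9))
        wrong = b.WeibullBoundaryParams(a=10.0, a_prime=10.0, lam=4.0, sigma2=0.2, x1=0.0)
        ll_wrong = b.sim_likelihood(trials, wrong, cfg, np.random.default_rng(9))
        assert ll_true > ll_wrong


class TestFit:
    def test_same_seed_identical_fit(self):
        rng = np.random.default_rng(10)
        trials = []
        for _ in range(15):
            d = np.where(rng.random(30) < 0.6, 1.0, -1.0)
            _, s, _ = b.simulate_accumulator(d, P_FIXED, rng, max_steps=40)
            trials.append((d, s))
        cfg = b.SimLikelihoodConfig(
            n_sim_per_trial=150, grid_points=4, grid_passes=1, simplex_starts=2,
            simplex_maxiter=40, max_steps=40, fix_x1=0.0, final_eval_factor=2,
        )
        f1 = b.fit_ml(trials, "fixed", cfg, seed=3)
        f2 = b.fit_ml(trials, "fixed", cfg, seed=3)
        assert f1.params == f2.params
        assert f1.loglik == f2.loglik

    def test_aic_accounting(self):
        rng = np.random.default_rng(11)
        trials = [(np.where(rng.random(30) < 0.6, 1.0, -1.0), 4) for _ in range(10)]
        cfg = b.SimLikelihoodConfig(
            n_sim_per_trial=150, grid_points=3, grid_passes=1, simplex_starts=1,
            simplex_maxiter=20, max_steps=30, fix_x1=0.0, final_eval_factor=2,
        )
        ffix = b.fit_ml(trials, "fixed", cfg, seed=0)
        fcol = b.fit_ml(trials, "collapsing", cfg, seed=0)
        assert ffix.n_free == 2 and fcol.n_free == 4
        assert ffix.aic == pytest.approx(2 * 2 - 2 * ffix.loglik)
        assert fcol.aic == pytest.approx(2 * 4 - 2 * fcol.loglik)

    def test_validation(self):
        with pytest.raises(ValueError):
            b.fit_ml([], "fixed")
        with pytest.raises(ValueError):
            b.fit_ml([(np.ones(3), 2)], "weird")
        with pytest.raises(ValueError):
            b.SimLikelihoodConfig(n_sim_per_trial=10)
        with pytest.raises(ValueError):
            b.SimLikelihoodConfig(epsilon_floor=-1.0)
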
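"""Reset protocols, reset application, and the empirical resetting oracles."""

import math

import numpy as np
import pytest

import resetfpt as rf


class TestProtocols:
    def test_validation(self):
        with pytest.raises(ValueError):
            rf.ResetProtocol("poisson")          # rate missing
        with pytest.raises(ValueError):
            rf.ResetProtocol("sharp", rate=1.0)  # wrong field
        with pytest.raises(ValueError):
            rf.ResetProtocol("none", period=1.0)
        with pytest.raises(ValueError):
            rf.ResetProtocol("weekly")

    def test_sharp_interval_is_exactly_the_period(self):
        proto = rf.sharp_resetting(40.0)
        rng = np.random.default_rng(0)
        assert all(rf.draw_reset_interval(proto, rng) == 40.0
                   for _ in range(10))

    def test_poisson_interval_mean(self):
        # r = 0.1 ns^-1 = 1e-4 ps^-1: mean interval 10 ns
        proto = rf.poisson_resetting(1e-4)
        rng = np.random.default_rng(1)
        draws = np.array([rf.draw_reset_interval(proto, rng)
                          for _ in range(100_000)])
        assert draws.mean() == pytest.approx(1e4, rel=0.02)

    def test_none_never_resets(self):
        assert math.isinf(rf.draw_reset_interval(rf.no_resetting(), 0))


class TestApplyReset:
    def test_point_reset_restores_position_and_clocks(self):
        init = rf.InitialCondition(position=[3.0], temperature=300.0,
                                   mass=40.0)
        state = rf.ParticleState(position=[-1.7], velocity=[2.2],
                                 elapsed_time=55.0, resets_so_far=2,
                                 time_since_last_reset=15.0)
        out = rf.apply_reset(state, init, np.random.default_rng(4))
        assert out.position[0] == 3.0
        assert out.elapsed_time == 55.0           # global clock preserved
        assert out.time_since_last_reset == 0.0
        assert out.resets_so_far == 3

    def test_reset_velocities_are_maxwell_boltzmann(self):
        init = rf.InitialCondition(position=[0.0], temperature=300.0,
                                   mass=40.0)
        state = rf.ParticleState(position=[1.0], velocity=[0.0])
        rng = np.random.default_rng(9)
        v = np.array([rf.apply_reset(state, init, rng).velocity[0]
                      for _ in range(10_000)])
        assert v.var() == pytest.approx(rf.KB * 300.0 / 40.0, rel=0.03)


class TestPoissonOracle:
    def test_memoryless_input_is_left_unchanged(self):
        tau = np.random.default_rng(2).exponential(50.0, 40_000)
        samples = rf.FPTSampleSet(tau=tau)
        for gamma in [1e-3, 0.02, 0.2]:
            mean, se = rf.empirical_poisson_reset_oracle(samples, gamma,
                                                         n_rep=40_000, rng=3)
            assert abs(mean - 50.0) < 4 * se + 0.02 * 50.0

    def test_degenerate_input_matches_renewal_closed_form(self):
        tau0, gamma = 5.0, 0.21
        samples = rf.FPTSampleSet(tau=np.full(1000, tau0))
        mean, se = rf.empirical_poisson_reset_oracle(samples, gamma,
                                                     n_rep=60_000, rng=5)
        expected = (math.exp(gamma * tau0) - 1.0) / gamma
        assert abs(mean - expected) < 3 * se

    def test_vanishing_rate_recovers_sample_mean(self):
        tau = np.random.default_rng(6).lognormal(3.0, 1.0, 5000)
        samples = rf.FPTSampleSet(tau=tau)
        gamma = 1e-3 / tau.mean() * 1e-3
        mean, se = rf.empirical_poisson_reset_oracle(samples, gamma,
                                                     n_rep=20_000, rng=7)
        assert mean == pytest.approx(tau.mean(), rel=0.05)

    def test_censored_input_rejected(self):
        samples = rf.FPTSampleSet(tau=np.array([1.0, 2.0]),
                                  censored=np.array([False, True]))
        with pytest.raises(rf.CensoredSamplesError):
            rf.empirical_poisson_reset_oracle(samples, 0.1)


class TestSharpEstimator:
    def test_period_beyond_support_gives_sample_mean(self):
        tau = np.array([1.0, 2.0, 5.0])
        samples = rf.FPTSampleSet(tau=tau)
        assert rf.empirical_sharp_reset_mean(samples, 100.0) == \
            pytest.approx(tau.mean())

    def test_degenerate_samples(self):
        samples = rf.FPTSampleSet(tau=np.full(10, 3.0))
        assert rf.empirical_sharp_reset_mean(samples, 8.0) == 3.0

    def test_impossible_period_rejected(self):
        samples = rf.FPTSampleSet(tau=np.array([5.0, 9.0]))
        with pytest.raises(ValueError, match="never finish"):
            rf.empirical_sharp_reset_mean(samples, 1.0)

    def test_matches_analytic_sharp_mean_on_ig_samples(self, ig_model,
                                                       ig_samples):
        rng = np.random.default_rng(12)
        tau = ig_samples.observed
        for period in [200.0, 500.0, 2000.0]:
            est = rf.empirical_sharp_reset_mean(ig_samples, period)
            exact = rf.exact_sharp_reset_mean(ig_model, period)
            # bootstrap SE of the plug-in renewal estimator
            boot = np.empty(120)
            for b in range(120):
                res = rf.FPTSampleSet(tau=rng.choice(tau, tau.size))
                boot[b] = rf.empirical_sharp_reset_mean(res, period)
            assert abs(est - exact) < 3 * boot.std(ddof=1)


class TestProtocolOrdering:
    @pytest.mark.parametrize("lam", [100.0, 250.0, 440.0])
    def test_optimal_sharp_beats_optimal_poisson(self, lam):
        # for every broad (COV > 1) model the best sharp protocol is at
        # least as fast as the best Poisson protocol
        model = rf.inverse_gaussian_model(1000.0, lam)
        assert model.cov > 1
        gammas = np.geomspace(0.05 / model.mean, 50.0 / model.mean, 400)
        best_poisson = min(rf.exact_poisson_reset_mean(model, g)
                           for g in gammas)
        periods = np.geomspace(model.mean / 50.0, 20.0 * model.mean, 400)
        best_sharp = min(rf.exact_sharp_reset_mean(model, t)
                         for t in periods)
        assert best_sharp <= best_poisson * (1.0 + 1e-9)


class TestCOVCriterion:
    @pytest.mark.parametrize("cov", [0.5, 0.9, 1.1, 2.0, 3.0])
    def test_small_rate_helps_iff_cov_above_one(self, cov):
        model = rf.inverse_gaussian_model(1000.0, 1000.0 / cov**2)
        assert model.cov == pytest.approx(cov)
        deriv = rf.poisson_rate_derivative_at_zero(model)
        if cov > 1:
            assert deriv < 0
        else:
            assert deriv > 0


class TestDirectSimulationConsistency:
    def test_double_well_poisson_run_matches_oracle(self, dw_spec,
                                                    dw_baseline):
        # simulating with resetting must agree with resetting applied to
        # reset-free samples through the renewal oracle
        base = rf.summarize(dw_baseline)
        rate = 2.0 / base.mean
        init, crit = rf.default_experiment("double_well_1d")
        cfg = rf.default_config("double_well_1d", max_time=2e5)
        direct = rf.run_ensemble(1500, dw_spec, init, crit,
                                 rf.poisson_resetting(rate), cfg,
                                 base_seed=55)
        s_direct = rf.summarize(direct)
        mean_oracle, se_oracle = rf.empirical_poisson_reset_oracle(
            dw_baseline, rate, n_rep=100_000, rng=21)
        combined = math.hypot(s_direct.se_mean, se_oracle)
        assert abs(s_direct.mean - mean_oracle) < 3 * combined
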
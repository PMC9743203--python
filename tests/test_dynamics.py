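"""Langevin integrator physics, passage detection, ensemble contracts."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

import resetfpt as rf
from resetfpt.dynamics import _FORM_IDS, _force_nb_probe, _pack_params


class TestMaxwellBoltzmann:
    def test_zero_temperature_gives_zero_velocities(self):
        v = rf.sample_maxwell_boltzmann(0.0, 40.0, 3, 1)
        assert np.all(v == 0.0)

    def test_variance_is_kt_over_m(self):
        T, m = 300.0, 40.0
        rng = np.random.default_rng(8)
        draws = rf.sample_maxwell_boltzmann(T, m, 100_000, rng)
        assert draws.var() == pytest.approx(rf.KB * T / m, rel=0.02)
        assert stats.normaltest(draws).pvalue > 0.01

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(rf.ConfigurationError):
            rf.sample_maxwell_boltzmann(300.0, 0.0, 1, 1)


class TestLangevinStep:
    def test_ballistic_limit(self):
        # zero force, zero friction: x advances by v*dt, clocks tick
        spec = rf.PotentialSpec(form="harmonic", parameters={"k": 0.0},
                                dimensionality=1)
        cfg = rf.SimulationConfig(dt=0.01, friction=0.0, temperature=300.0,
                                  mass=1.0, max_time=1.0)
        state = rf.ParticleState(position=[2.0], velocity=[5.0])
        out = rf.langevin_step(state, spec, cfg, np.random.default_rng(0))
        assert out.position[0] == pytest.approx(2.0 + 5.0 * 0.01)
        assert out.velocity[0] == pytest.approx(5.0)
        assert out.elapsed_time == pytest.approx(0.01)
        assert out.time_since_last_reset == pytest.approx(0.01)

    def test_equipartition_in_harmonic_well(self):
        # pooled positions from 200 walkers x 5000 steps (1e6 total)
        k, m, gamma, T = 100.0, 1.0, 10.0, 300.0
        spec = rf.PotentialSpec(form="harmonic", parameters={"k": k},
                                dimensionality=1)
        cfg = rf.SimulationConfig(dt=0.004, temperature=T, friction=gamma,
                                  mass=m, max_time=1.0)
        x = rf.sample_equilibrium(spec, cfg, [0.0], n_walkers=200,
                                  n_steps=5000, burn_in=1000,
                                  sample_stride=50, base_seed=31)
        assert x.var() == pytest.approx(rf.KB * T / k, rel=0.03)

    def test_infinite_friction_decorrelates_velocity_in_one_step(self):
        spec = rf.PotentialSpec(form="harmonic", parameters={"k": 0.0},
                                dimensionality=1)
        cfg = rf.SimulationConfig(dt=0.004, temperature=300.0, friction=2e3,
                                  mass=1.0, max_time=1.0)
        rng = np.random.default_rng(5)
        state = rf.ParticleState(position=[0.0],
                                 velocity=rf.sample_maxwell_boltzmann(
                                     300.0, 1.0, 1, rng))
        v = []
        for _ in range(4000):
            state = rf.ParticleState(position=[0.0], velocity=state.velocity)
            state = rf.langevin_step(state, spec, cfg, rng)
            v.append(state.velocity[0])
        v = np.asarray(v)
        autocorr = np.corrcoef(v[:-1], v[1:])[0, 1]
        assert abs(autocorr) < 0.05


class TestRunFirstPassage:
    def _flat_spec(self):
        return rf.PotentialSpec(form="harmonic", parameters={"k": 0.0},
                                dimensionality=1)

    def test_instant_passage_when_allowed(self):
        init = rf.InitialCondition(position=[-5.0], allow_initial_passage=True)
        crit = rf.PassageCriterion(index=0, direction="<=", threshold=-3.0)
        cfg = rf.SimulationConfig(max_time=1.0)
        rec = rf.run_first_passage(self._flat_spec(), init, crit, None, cfg, 0)
        assert rec.tau == 0.0 and not rec.censored

    def test_instant_passage_rejected_by_default(self):
        init = rf.InitialCondition(position=[-5.0])
        crit = rf.PassageCriterion(index=0, direction="<=", threshold=-3.0)
        cfg = rf.SimulationConfig(max_time=1.0)
        with pytest.raises(ValueError, match="already satisfies"):
            rf.run_first_passage(self._flat_spec(), init, crit, None, cfg, 0)

    def test_unreachable_threshold_censors_at_max_time(self):
        init = rf.InitialCondition(position=[0.0], temperature=300.0, mass=40.0)
        crit = rf.PassageCriterion(index=0, direction=">=", threshold=1e6)
        cfg = rf.SimulationConfig(dt=0.004, max_time=0.04)
        rec = rf.run_first_passage(self._flat_spec(), init, crit, None, cfg, 3)
        assert rec.censored and rec.tau == cfg.max_time


class TestEnsembles:
    def test_same_seed_reproduces_sample_sets(self, dw_spec):
        init, crit = rf.default_experiment("double_well_1d")
        cfg = rf.default_config("double_well_1d", max_time=1e5)
        a = rf.run_ensemble(100, dw_spec, init, crit, None, cfg, base_seed=9)
        b = rf.run_ensemble(100, dw_spec, init, crit, None, cfg, base_seed=9)
        np.testing.assert_array_equal(a.tau, b.tau)
        np.testing.assert_array_equal(a.censored, b.censored)

    def test_prefix_stability_under_ensemble_extension(self, dw_spec):
        # per-trajectory RNG streams depend only on (base_seed, index), so a
        # larger ensemble extends a smaller one without altering it
        init, crit = rf.default_experiment("double_well_1d")
        cfg = rf.default_config("double_well_1d", max_time=1e5)
        small = rf.run_ensemble(20, dw_spec, init, crit, None, cfg, base_seed=9)
        large = rf.run_ensemble(60, dw_spec, init, crit, None, cfg, base_seed=9)
        np.testing.assert_array_equal(small.tau, large.tau[:20])

    def test_kernel_forces_match_reference_implementation(self):
        rng = np.random.default_rng(17)
        for form, fid in _FORM_IDS.items():
            spec = rf.default_spec(form)
            box = np.asarray(spec.box)
            pts = rng.uniform(box[:, 0] * 0.4, box[:, 1] * 0.4,
                              (25, spec.dimensionality))
            for pt in pts:
                ref = np.atleast_1d(rf.potential_force(spec, pt))
                nb = _force_nb_probe(fid, _pack_params(spec),
                                     pt.astype(np.float64))
                np.testing.assert_allclose(nb, ref, rtol=1e-12, atol=1e-12)

    def test_double_well_mean_fpt_robust_to_halving_dt(self, dw_spec,
                                                       dw_baseline):
        init, crit = rf.default_experiment("double_well_1d")
        fine_cfg = rf.default_config("double_well_1d", dt=0.002, max_time=2e5)
        fine = rf.run_ensemble(2000, dw_spec, init, crit, None, fine_cfg,
                               base_seed=77)
        s_ref = rf.summarize(dw_baseline)
        s_fine = rf.summarize(fine)
        combined_se = math.hypot(s_ref.se_mean, s_fine.se_mean)
        assert abs(s_ref.mean - s_fine.mean) < 3 * combined_se

    def test_pilot_sets_time_budget_when_unspecified(self, dw_spec):
        init, crit = rf.default_experiment("double_well_1d")
        cfg = rf.default_config("double_well_1d")  # max_time = None
        s = rf.run_ensemble(50, dw_spec, init, crit, None, cfg, base_seed=6)
        budget = s.metadata["max_time"]
        # 100x a pilot mean: generously above typical passage times
        assert budget > 20 * np.mean(s.observed)
        assert np.all(s.tau[~s.censored] <= budget)

    def test_censoring_is_loud_and_counted(self, dw_spec):
        init, crit = rf.default_experiment("double_well_1d")
        cfg = rf.default_config("double_well_1d", max_time=1.0)
        with pytest.warns(UserWarning, match="censored"):
            s = rf.run_ensemble(20, dw_spec, init, crit, None, cfg,
                                base_seed=2)
        assert s.n_censored > 0
        assert np.all(s.tau[s.censored] == 1.0)

    def test_rare_escape_holding_times_are_memoryless(self):
        # escape from a harmonic trap to a threshold ~6 kT up the wall is a
        # rare event; its FPT distribution approaches exponential (COV -> 1)
        spec = rf.PotentialSpec(form="harmonic", parameters={"k": 10.0},
                                dimensionality=1)
        init = rf.InitialCondition(position=[0.0], temperature=300.0,
                                   mass=1.0)
        crit = rf.PassageCriterion(index=0, direction=">=", threshold=17.5)
        cfg = rf.SimulationConfig(dt=0.004, friction=5.0, mass=1.0,
                                  max_time=1e5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = rf.run_ensemble(1200, spec, init, crit, None, cfg,
                                base_seed=41)
        summ = rf.summarize(s)
        assert summ.cov == pytest.approx(1.0, abs=0.12)
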
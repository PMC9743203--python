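"""Potential surfaces: energies, forces, stationary points, constraints."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import resetfpt as rf
from resetfpt.potentials import default_constraints

ALL_FORMS = ["harmonic", "double_well_1d", "entropic_two_basin_2d",
             "modified_wolfe_quapp_2d"]


def finite_difference_force(spec, point, h=1e-5):
    point = np.atleast_1d(np.asarray(point, float))
    out = np.empty_like(point)
    for ax in range(point.size):
        e = np.zeros_like(point)
        e[ax] = h * max(1.0, abs(point[ax]))
        out[ax] = -(rf.potential_energy(spec, point + e)
                    - rf.potential_energy(spec, point - e)) / (2 * e[ax])
    return out


class TestEnergyAndForce:
    def test_harmonic_closed_form(self):
        spec = rf.PotentialSpec(form="harmonic", parameters={"k": 2.0},
                                dimensionality=1)
        assert rf.potential_energy(spec, 3.0) == pytest.approx(9.0)
        assert float(rf.potential_force(spec, 3.0)) == pytest.approx(-6.0)

    def test_double_well_barrier_is_one_kt(self, dw_spec):
        u0 = rf.potential_energy(dw_spec, 0.0)
        umin = rf.potential_energy(dw_spec, 3.0)
        assert (u0 - umin) / dw_spec.kbt == pytest.approx(1.0, rel=1e-9)

    @given(x=st.floats(-120.0, 120.0, allow_nan=False))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_double_well_parity(self, x):
        spec = rf.default_spec("double_well_1d")
        assert rf.potential_energy(spec, x) == pytest.approx(
            rf.potential_energy(spec, -x), abs=1e-10 * max(1.0, abs(x)))

    def test_entropic_y_reflection_symmetry(self):
        spec = rf.default_spec("entropic_two_basin_2d")
        pts = np.random.default_rng(0).uniform([-3, -100], [3, 100], (40, 2))
        up = rf.potential_energy(spec, pts)
        down = rf.potential_energy(spec, pts * np.array([1.0, -1.0]))
        np.testing.assert_allclose(up, down, rtol=1e-12)

    @pytest.mark.parametrize("form", ALL_FORMS + ["custom"])
    def test_force_matches_finite_differences(self, form):
        if form == "custom":
            spec = rf.PotentialSpec(
                form="custom_expression",
                parameters={"expression": "0.5*x**2 + sin(y) + x*y"},
                dimensionality=2, box=((-5, 5), (-5, 5)))
        else:
            spec = rf.default_spec(form)
        rng = np.random.default_rng(7)
        box = np.asarray(spec.box)
        pts = rng.uniform(box[:, 0] * 0.4, box[:, 1] * 0.4,
                          (40, spec.dimensionality))
        for pt in pts:
            analytic = np.atleast_1d(rf.potential_force(spec, pt))
            fd = finite_difference_force(spec, pt)
            np.testing.assert_allclose(analytic, fd, rtol=1e-5,
                                       atol=1e-5 * np.abs(fd).max() + 1e-8)

    def test_force_vanishes_at_minima(self):
        for form in ALL_FORMS:
            spec = rf.default_spec(form)
            guesses = {"harmonic": [0.5], "double_well_1d": [2.0],
                       "entropic_two_basin_2d": [(1.0, 0.2)],
                       "modified_wolfe_quapp_2d": [(-14.0, -1.0)]}[form]
            for minimum in rf.find_minima(spec, guesses):
                assert np.linalg.norm(rf.potential_force(spec, minimum)) < 1e-6

    def test_unknown_form_and_missing_parameter(self):
        with pytest.raises(rf.ConfigurationError, match="unknown"):
            rf.PotentialSpec(form="nonexistent", parameters={})
        with pytest.raises(rf.ConfigurationError, match="sigma"):
            rf.PotentialSpec(form="double_well_1d",
                             parameters={"k": 1.0, "A": 1.0},
                             dimensionality=1)

    def test_dimension_mismatch_rejected(self):
        spec = rf.default_spec("entropic_two_basin_2d")
        with pytest.raises(rf.ConfigurationError):
            rf.potential_energy(spec, np.zeros(3))


class TestStationaryPoints:
    def test_double_well_minima_at_pm3(self, dw_spec):
        minima = sorted(float(m[0]) for m in
                        rf.find_minima(dw_spec, [-2.0, 2.0, 2.5]))
        assert minima == pytest.approx([-3.0, 3.0], abs=0.1)

    def test_entropic_minima(self):
        spec = rf.default_spec("entropic_two_basin_2d")
        minima = rf.find_minima(spec, [(1.0, 0.1), (-1.0, -0.1)])
        found = sorted(tuple(np.round(m, 3)) for m in minima)
        assert np.allclose(found[0], (-1.3, 0.0), atol=0.1)
        assert np.allclose(found[1], (1.3, 0.0), atol=0.1)

    def test_harmonic_single_minimum_with_merging(self):
        spec = rf.PotentialSpec(form="harmonic", parameters={"k": 2.0},
                                dimensionality=1)
        assert len(rf.find_minima(spec, [-1.0, 0.5, 1.0])) == 1

    def test_double_well_barrier_value(self, dw_spec):
        barrier, warn = rf.barrier_height(dw_spec, [-3.0], [3.0])
        assert not warn
        assert barrier == pytest.approx(1.0, rel=0.05)

    def test_entropic_barrier_value(self):
        spec = rf.default_spec("entropic_two_basin_2d")
        barrier, warn = rf.barrier_height(spec, [-1.3, 0.0], [1.3, 0.0])
        assert not warn
        assert barrier == pytest.approx(3.0, rel=0.05)

    def test_barrier_scales_linearly_with_energy_parameters(self, dw_spec):
        doubled = rf.PotentialSpec(
            form="double_well_1d",
            parameters={k: 2 * v for k, v in dw_spec.parameters.items()
                        if k != "sigma"} | {"sigma": dw_spec.parameters["sigma"]},
            dimensionality=1)
        b1, _ = rf.barrier_height(dw_spec, [-3.0], [3.0])
        b2, _ = rf.barrier_height(doubled, [-3.0], [3.0])
        assert b2 == pytest.approx(2 * b1, rel=1e-6)

    def test_no_interior_maximum_flags_zero_barrier(self):
        spec = rf.PotentialSpec(form="harmonic", parameters={"k": 2.0},
                                dimensionality=1)
        barrier, warn = rf.barrier_height(spec, [0.0], [0.0])
        assert warn and barrier == 0.0


class TestConstraintVerification:
    @pytest.mark.parametrize("form", ["double_well_1d",
                                      "entropic_two_basin_2d",
                                      "modified_wolfe_quapp_2d"])
    def test_shipped_defaults_pass_all_printed_constraints(self, form):
        spec = rf.default_spec(form)
        report = rf.verify_constraints(spec, default_constraints(form))
        assert report.all_passed, str(report)

    def test_entropic_width_ratio_near_100(self):
        spec = rf.default_spec("entropic_two_basin_2d")
        wide = rf.basin_width(spec, (1.3, 0.0), axis=1)
        narrow = rf.basin_width(spec, (-1.3, 0.0), axis=1)
        assert wide / narrow == pytest.approx(100.0, rel=0.05)

    def test_wolfe_quapp_direct_escape_barriers_asymmetric(self):
        spec = rf.default_spec("modified_wolfe_quapp_2d")
        left = rf.slice_barrier(spec, (-15.0, -1.4), (-15.0, 1.4))
        right = rf.slice_barrier(spec, (15.0, -1.4), (15.0, 1.4))
        assert left == pytest.approx(6.25, rel=0.07)
        assert right == pytest.approx(10.0, rel=0.07)

    def test_harmonic_fails_a_barrier_constraint(self):
        spec = rf.PotentialSpec(form="harmonic", parameters={"k": 2.0},
                                dimensionality=1)
        report = rf.verify_constraints(
            spec, [("barrier_kt", 1.0, 0.05, -0.5, 0.5)])
        assert not report.all_passed
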
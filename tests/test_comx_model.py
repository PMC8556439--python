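import numpy as np
import pytest

from comxdyn.comx_model import (
    ComXModelParams,
    sensitivity_envelope,
    simulate,
    steady_state,
)
from comxdyn.curvefit import ConstantCurve, SigmoidCurve
from comxdyn.exceptions import DomainError, NoSteadyStateError


def euler_oracle(params, biomass, t_end, ea0=0.0, dt=1e-3):
    """Independent fixed-step forward-Euler integration."""
    n = int(round(t_end / dt))
    t = np.linspace(0.0, t_end, n + 1)
    x = np.asarray(biomass.predict(t), dtype=float)
    dx = np.asarray(biomass.derivative(t), dtype=float)
    a = np.empty(n + 1)
    ea = np.empty(n + 1)
    a[0], ea[0] = params.a0, ea0
    for i in range(n):
        a[i + 1] = a[i] + dt * (
            params.b * x[i] + params.d * dx[i] - params.e * ea[i]
        )
        ea[i + 1] = ea[i] + dt * (params.f * a[i] - params.g * ea[i])
    return t, a, ea


class TestSimulate:
    def test_zero_biomass_protease_relaxes_to_f_over_g(self, midpoint_params):
        # with e = 0 the activity stays at a0 and the protease relaxes to
        # (f/g) * a0 = 9.29 for a0 = 26.5
        params = midpoint_params.with_values(e=0.0)
        t = np.linspace(0, 200, 101)
        traj = simulate(params, 0.0, t, ea0=0.0)
        np.testing.assert_allclose(traj.a_comx, params.a0, rtol=1e-7)
        assert traj.ea_csp[-1] == pytest.approx(
            params.f * params.a0 / params.g, rel=1e-6
        )
        assert traj.ea_csp[-1] == pytest.approx(9.29, abs=0.01)

    def test_pure_growth_term_integrates_biomass_change(self, midpoint_params,
                                                        logistic_biomass):
        params = midpoint_params.with_values(b=0.0, e=0.0)
        t = np.linspace(0, 48, 49)
        traj = simulate(params, logistic_biomass, t)
        x = logistic_biomass.predict(t)
        expected = params.a0 + params.d * (x - x[0])
        np.testing.assert_allclose(traj.a_comx, expected, rtol=1e-6)

    def test_constant_biomass_converges_to_steady_state(self, midpoint_params):
        t = np.linspace(0, 200, 201)
        traj = simulate(midpoint_params, 5.4, t)
        a_ss, ea_ss = steady_state(midpoint_params, 5.4)
        assert a_ss == pytest.approx(197.34, abs=0.05)
        assert traj.a_comx[-1] == pytest.approx(a_ss, rel=1e-3)
        assert traj.ea_csp[-1] == pytest.approx(ea_ss, rel=1e-3)

    def test_euler_oracle_equivalence(self, midpoint_params, logistic_biomass):
        t, a_euler, _ = euler_oracle(midpoint_params, logistic_biomass, 48.0)
        traj = simulate(midpoint_params, logistic_biomass, t)
        sup = np.max(np.abs(traj.a_comx - np.maximum(a_euler, 0.0)))
        assert sup <= 1e-3 * np.max(np.abs(a_euler))

    def test_superposition_of_forcings(self, midpoint_params):
        # linear in (a, EA) given the forcing: doubling the biomass doubles
        # the zero-initial-condition response
        t = np.linspace(0, 48, 97)
        base = midpoint_params.with_values(a0=0.0)
        one = simulate(base, 2.7, t, ea0=0.0)
        two = simulate(base, 5.4, t, ea0=0.0)
        np.testing.assert_allclose(two.a_comx, 2 * one.a_comx, rtol=1e-6,
                                   atol=1e-8)

    def test_peak_then_settle(self, midpoint_params, logistic_biomass):
        t = np.linspace(0, 48, 481)
        traj = simulate(midpoint_params, logistic_biomass, t)
        i_peak = np.argmax(traj.a_comx)
        i_growth = np.argmax(logistic_biomass.derivative(t))
        assert t[i_peak] > t[i_growth]
        assert traj.a_comx[i_peak] > traj.a_comx[-1]

    def test_negative_biomass_rejected(self, midpoint_params):
        with pytest.raises(DomainError):
            simulate(midpoint_params, -1.0, [0.0, 1.0])

    def test_unsorted_grid_rejected(self, midpoint_params):
        with pytest.raises(DomainError):
            simulate(midpoint_params, 1.0, [0.0, 2.0, 1.0])


class TestSteadyState:
    def test_zero_biomass(self, midpoint_params):
        assert steady_state(midpoint_params, 0.0) == (0.0, 0.0)

    def test_midpoint_values(self, midpoint_params):
        a_ss, ea_ss = steady_state(midpoint_params, 5.4)
        assert a_ss == pytest.approx(197.34, abs=0.01)
        assert ea_ss == pytest.approx(69.19, abs=0.01)

    def test_linearity_in_b(self, midpoint_params):
        a1, _ = steady_state(midpoint_params, 5.4)
        a2, _ = steady_state(midpoint_params.with_values(b=2 * midpoint_params.b),
                             5.4)
        assert a2 == pytest.approx(2 * a1)

    def test_no_steady_state_without_degradation(self, midpoint_params):
        with pytest.raises(NoSteadyStateError):
            steady_state(midpoint_params.with_values(e=0.0), 5.4)


class TestSensitivityEnvelope:
    def test_zero_fraction_collapses(self, midpoint_params, logistic_biomass,
                                     hour_grid):
        band = sensitivity_envelope(midpoint_params, logistic_biomass,
                                    hour_grid, frac=0.0)
        np.testing.assert_array_equal(band.lower, band.nominal)
        np.testing.assert_array_equal(band.upper, band.nominal)

    def test_nominal_inside_band(self, midpoint_params, logistic_biomass,
                                 hour_grid):
        band = sensitivity_envelope(midpoint_params, logistic_biomass,
                                    hour_grid, frac=0.08)
        assert np.all(band.lower <= band.nominal + 1e-12)
        assert np.all(band.nominal <= band.upper + 1e-12)

    def test_band_nestedness(self, midpoint_params, logistic_biomass,
                             hour_grid):
        narrow = sensitivity_envelope(midpoint_params, logistic_biomass,
                                      hour_grid, frac=0.04)
        wide = sensitivity_envelope(midpoint_params, logistic_biomass,
                                    hour_grid, frac=0.08)
        assert np.all(wide.lower <= narrow.lower + 1e-9)
        assert np.all(narrow.upper <= wide.upper + 1e-9)


def test_params_validation():
    with pytest.raises(DomainError):
        ComXModelParams(b=-1.0)
    with pytest.raises(DomainError):
        ComXModelParams(g=0.0)
    mid = ComXModelParams.midpoint()
    assert mid.f == 0.115 and mid.g == 0.328
    assert mid.free_names == ("a0", "b", "d", "e")
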
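import numpy as np
import pandas as pd
import pytest

from comxdyn.curvefit import SigmoidCurve
from comxdyn.dataio import CultivationTimeSeries
from comxdyn.exceptions import DomainError
from comxdyn.metrics import (
    growth_rate,
    max_growth_rate,
    overall_specific_productivity,
    process_metrics,
    q_vs_comx,
    specific_productivity,
    t_at_fraction,
    yield_biomass_substrate,
    yield_product_biomass,
    yield_product_substrate,
)
from comxdyn.synthgen import SynthConfig, generate_cultivation


def make_series(time, cdw=None, glucose=None, surfactin=None, comx=None):
    cols = {"time_h": time, "replicate": "R1"}
    if cdw is not None:
        cols["cdw_g_L"] = cdw
    if glucose is not None:
        cols["glucose_g_L"] = glucose
    if surfactin is not None:
        cols["surfactin_mg_L"] = surfactin
    if comx is not None:
        cols["comx_MU"] = comx
    return CultivationTimeSeries(pd.DataFrame(cols))


class TestTAtFraction:
    def test_full_fraction_gives_time_of_maximum(self):
        assert t_at_fraction([0, 10, 20], [0, 5, 5], 1.0) == 10.0

    def test_ninety_percent_not_yet_reached(self):
        assert t_at_fraction([0, 10, 20], [0, 4, 5], 0.9) == 20.0

    def test_ninety_percent_reached_early(self):
        assert t_at_fraction([0, 10, 20], [0, 4.6, 5], 0.9) == 10.0


REFERENCE = make_series(
    time=[0.0, 40.0],
    cdw=[0.031, 5.4],
    glucose=[40.0, 4.0],
    surfactin=[0.0, 1346.6],
)


class TestYields:
    def test_biomass_substrate_reference_process(self):
        got = yield_biomass_substrate(REFERENCE, 40.0)
        assert got == pytest.approx(0.149, abs=0.001)

    def test_product_substrate_reference_process(self):
        got = yield_product_substrate(REFERENCE, 40.0)
        assert got == pytest.approx(0.0374, abs=0.0005)

    def test_product_biomass_reference_process(self):
        got = yield_product_biomass(REFERENCE, 40.0, 40.0)
        assert got == pytest.approx(0.496, abs=0.001)

    def test_zero_biomass_change(self):
        series = make_series([0.0, 10.0], cdw=[1.0, 1.0], glucose=[40.0, 30.0])
        assert yield_biomass_substrate(series, 10.0) == 0.0

    def test_no_substrate_consumed(self):
        series = make_series([0.0, 10.0], cdw=[1.0, 2.0], glucose=[40.0, 40.0])
        with pytest.raises(DomainError):
            yield_biomass_substrate(series, 10.0)

    def test_scale_invariance(self):
        a = make_series([0, 10], cdw=[0.1, 2.1], glucose=[20.0, 10.0])
        b = make_series([0, 10], cdw=[0.2, 4.2], glucose=[40.0, 20.0])
        assert yield_biomass_substrate(a, 10.0) == pytest.approx(
            yield_biomass_substrate(b, 10.0)
        )


class TestGrowthRate:
    def test_doubling_in_one_hour(self):
        assert growth_rate(1.0, 2.0, 0.0, 1.0) == pytest.approx(np.log(2))

    def test_no_growth(self):
        assert growth_rate(2.0, 2.0, 0.0, 5.0) == 0.0

    def test_mu_max_doubling_every_two_hours(self):
        t = np.arange(0, 11, 2.0)
        x = 0.1 * 2 ** (t / 2)
        assert max_growth_rate(t, x) == pytest.approx(np.log(2) / 2, rel=1e-9)

    def test_nonpositive_biomass(self):
        with pytest.raises(DomainError):
            growth_rate(0.0, 1.0, 0.0, 1.0)


class TestSpecificProductivity:
    def test_interval_formula(self):
        assert specific_productivity(1.0, 1.0, 3.0, 1.0) == pytest.approx(0.5)

    def test_zero_product(self):
        assert specific_productivity(0.0, 1.0, 3.0, 2.0) == 0.0

    def test_reference_process_overall(self):
        got = overall_specific_productivity(REFERENCE)
        assert got == pytest.approx(1.3466 / (2.7155 * 40), rel=1e-6)

    def test_internal_consistency_with_endpoints(self):
        series = make_series(
            time=[0.0, 10.0, 20.0, 30.0],
            cdw=[0.1, 2.0, 5.0, 5.2],
            glucose=[40.0, 30.0, 10.0, 5.0],
            surfactin=[0.0, 200.0, 900.0, 1000.0],
        )
        t_p90 = t_at_fraction(series.time, series.surfactin, 0.9)
        t_x90 = t_at_fraction(series.time, series.cdw, 0.9)
        dp = (900.0 - 0.0) / 1000.0
        expected = specific_productivity(dp, 0.1, 5.0, t_p90 - 0.0)
        assert t_p90 == 20.0 and t_x90 == 20.0
        assert overall_specific_productivity(series) == pytest.approx(expected)


class TestQvsComX:
    def test_constant_surfactin_gives_zero(self):
        biomass = SigmoidCurve.from_params(0.1, 5.0, 12.0, 2.0)
        surf = SigmoidCurve.from_params(500.0, 0.0, 20.0, 3.0)
        comx = SigmoidCurve.from_params(20.0, 200.0, 14.0, 2.0)
        curve = q_vs_comx(biomass, surf, comx, np.linspace(0, 48, 97))
        np.testing.assert_allclose(curve.q_surfactin, 0.0, atol=1e-12)

    def test_qmax_precedes_comx_peak(self):
        # productivity peaks near 9 h while the pheromone keeps rising
        # until ~16 h: the correlation is non-linear
        biomass = SigmoidCurve.from_params(0.031, 5.4, 10.0, 1.9)
        surf = SigmoidCurve.from_params(0.0, 1346.6, 9.0, 1.5)
        comx = SigmoidCurve.from_params(20.0, 200.0, 13.0, 1.5)
        t = np.linspace(0, 16.0, 321)
        curve = q_vs_comx(biomass, surf, comx, t)
        assert curve.t_at_qmax < 16.0
        assert curve.t_at_qmax < curve.t[np.argmax(curve.comx)] + 1e-9
        assert curve.comx_at_qmax < curve.comx.max()

    def test_time_unit_invariance_of_qmax(self):
        biomass = SigmoidCurve.from_params(0.031, 5.4, 10.0, 1.9)
        surf = SigmoidCurve.from_params(0.0, 1346.6, 9.0, 1.5)
        comx = SigmoidCurve.from_params(20.0, 200.0, 13.0, 1.5)
        t = np.linspace(0, 20, 101)
        q_hours = q_vs_comx(biomass, surf, comx, t).q_max
        # same curves in minutes: rates scale by 1/60
        biomass_m = SigmoidCurve.from_params(0.031, 5.4, 600.0, 114.0)
        surf_m = SigmoidCurve.from_params(0.0, 1346.6, 540.0, 90.0)
        comx_m = SigmoidCurve.from_params(20.0, 200.0, 780.0, 90.0)
        q_minutes = q_vs_comx(biomass_m, surf_m, comx_m, t * 60).q_max
        assert q_minutes * 60 == pytest.approx(q_hours, rel=1e-9)

    def test_nonpositive_biomass_rejected(self):
        biomass = SigmoidCurve.from_params(-1.0, 5.0, 12.0, 2.0)  # negative early
        surf = SigmoidCurve.from_params(0.0, 100.0, 10.0, 2.0)
        comx = SigmoidCurve.from_params(0.0, 100.0, 10.0, 2.0)
        with pytest.raises(DomainError):
            q_vs_comx(biomass, surf, comx, np.linspace(-100, 10, 20))

    def test_matches_generator_analytic_productivity(self):
        cfg = SynthConfig()
        _, truth = generate_cultivation(cfg)
        t = np.linspace(0.5, 16.0, 64)
        curve = q_vs_comx(
            truth.biomass_curve, truth.surfactin_curve,
            SigmoidCurve.from_params(20.0, 200.0, 20.0, 2.0), t,
        )
        expected = truth.q_surfactin(curve.t)
        sup = np.max(np.abs(curve.q_surfactin - expected))
        assert sup <= 0.02 * np.max(np.abs(expected))


def test_process_metrics_on_synthetic_reference():
    cfg = SynthConfig(seed=4)
    series, _ = generate_cultivation(cfg)
    pm = process_metrics(series)
    assert pm.x_max == pytest.approx(5.4, rel=0.1)
    assert pm.p_max == pytest.approx(1346.6, rel=0.1)
    assert 0.10 <= pm.y_xs <= 0.20
    assert pm.mu_max > 0.3
    assert pm.t_x90 <= 48.0 and pm.t_p90 <= 48.0
    assert pm.q_overall > 0
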
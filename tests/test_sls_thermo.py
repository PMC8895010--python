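"""Osmotic-virial (Debye plot) fitting and excess free-energy integration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.constants import Avogadro, R as R_gas
from scipy.integrate import quad

import mesocluster as mc
from mesocluster.errors import (
    DegenerateDataError,
    InvalidArgumentError,
    UnderdeterminedFitError,
)


def make_series(c_mg, y, sigma=None):
    return mc.ConcentrationSeries(concentration=c_mg, value=y, unit="mg/ml", sigma=sigma)


class TestOpticalConstant:
    def test_matches_closed_form_for_methanol_setup(self):
        # Independent hand evaluation of K = 4π²n²(dn/dc)²/(N_A λ⁴).
        expected = 4 * np.pi**2 * 1.325**2 * 0.275**2 / (Avogadro * 633e-9**4)
        assert mc.optical_constant(1.325, 0.275, 633e-9) == pytest.approx(expected, rel=1e-14)

    def test_scaling_laws(self):
        base = mc.optical_constant(1.3, 0.2, 500e-9)
        assert mc.optical_constant(1.3, 0.4, 500e-9) == pytest.approx(4 * base, rel=1e-12)
        assert mc.optical_constant(1.3, 0.2, 250e-9) == pytest.approx(16 * base, rel=1e-12)

    @pytest.mark.parametrize("args", [(-1, 0.2, 5e-7), (1.3, 0, 5e-7), (1.3, 0.2, -1)])
    def test_rejects_nonpositive_inputs(self, args):
        with pytest.raises(InvalidArgumentError):
            mc.optical_constant(*args)


class TestConcentrationSeries:
    def test_rejects_unsorted_or_nonpositive_concentrations(self):
        with pytest.raises(InvalidArgumentError):
            make_series([2.0, 1.0], [1.0, 1.0])
        with pytest.raises(InvalidArgumentError):
            make_series([0.0, 1.0], [1.0, 1.0])

    def test_rejects_length_mismatch_and_bad_unit(self):
        with pytest.raises(InvalidArgumentError):
            make_series([1.0, 2.0], [1.0])
        with pytest.raises(InvalidArgumentError):
            mc.ConcentrationSeries([1.0], [1.0], unit="furlong")

    def test_unit_conversions(self):
        s = make_series([10.0, 20.0], [1.0, 1.0])
        np.testing.assert_allclose(s.conc_g_per_ml, [0.01, 0.02])
        np.testing.assert_allclose(s.to_molar(200.0), [0.05, 0.10])


class TestFitVirial:
    def test_constant_series_is_ideal_solution(self):
        c = np.linspace(5.0, 90.0, 10)
        fit = mc.fit_virial(make_series(c, np.full(10, 1.0e-5)))
        assert fit.Mw_app == pytest.approx(1.0e5, rel=1e-10)
        assert fit.A2 == pytest.approx(0.0, abs=1e-12)
        assert fit.A3 == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_round_trip(self):
        mw, a2 = 2.0e4, 3.0e-4
        c_mg = np.linspace(10.0, 98.2, 12)
        c = c_mg * 1e-3
        y = 1.0 / mw + 2 * a2 * c
        fit = mc.fit_virial(make_series(c_mg, y))
        assert fit.Mw_app == pytest.approx(mw, rel=1e-3)
        assert fit.A2 == pytest.approx(a2, rel=1e-3)
        assert fit.A3 == pytest.approx(0.0, abs=1e-10)

    def test_refit_on_own_predictions_is_fixed_point(self):
        fit = mc.fit_virial(mc.gen_sls(mc.GeneratorConfig(seed=7)))
        c_mg = np.linspace(10.0, 98.2, 12)
        refit = mc.fit_virial(make_series(c_mg, fit.predict(c_mg * 1e-3)))
        assert refit.Mw_app == pytest.approx(fit.Mw_app, rel=1e-8)
        assert refit.A2 == pytest.approx(fit.A2, rel=1e-6, abs=1e-12)

    def test_noisy_recovery_within_three_standard_errors(self):
        cfg = mc.GeneratorConfig(seed=11)
        fit = mc.fit_virial(mc.gen_sls(cfg))
        se = fit.standard_errors
        assert abs(fit.Mw_app - cfg.Mw) < 3 * se[0]
        assert abs(fit.A2 - cfg.A2) < 3 * se[1]

    def test_monte_carlo_mw_recovery(self):
        # Median relative error of the apparent molar mass over 200 noisy
        # replicates at the 2% instrument noise level stays below 2%.
        errs = []
        for seed in range(200):
            fit = mc.fit_virial(mc.gen_sls(mc.GeneratorConfig(seed=seed)))
            errs.append(abs(fit.Mw_app - 193.25) / 193.25)
        assert np.median(errs) < 0.02

    def test_underdetermined_and_degenerate_signals(self):
        with pytest.raises(UnderdeterminedFitError):
            mc.fit_virial(make_series([1.0, 2.0, 3.0], [1e-5, 1e-5, 1e-5]))
        near = 50.0 + np.arange(6) * 1e-12  # six numerically coincident points
        with pytest.raises((DegenerateDataError, UnderdeterminedFitError)):
            mc.fit_virial(make_series(near, np.full(6, 1e-5)))


class TestOsmoticPressureDerivative:
    def test_ideal_fit_gives_vant_hoff_constant(self):
        c = np.linspace(5.0, 90.0, 8)
        fit = mc.fit_virial(make_series(c, np.full(8, 2.0e-5)))
        vals = [mc.osmotic_pressure_derivative(fit, cc) for cc in (0.01, 0.05, 0.09)]
        expected = R_gas * fit.temperature / fit.Mw_app
        np.testing.assert_allclose(vals, expected, rtol=1e-10)

    def test_strictly_increasing_for_positive_a2(self):
        c_mg = np.linspace(10.0, 98.2, 12)
        c = c_mg * 1e-3
        fit = mc.fit_virial(make_series(c_mg, 1 / 193.25 + 2 * 8e-3 * c))
        grid = np.linspace(0.01, 0.09, 30)
        dPi = mc.osmotic_pressure_derivative(fit, grid)
        assert np.all(np.diff(dPi) > 0)

    def test_matches_finite_difference_of_integrated_pressure(self):
        c_mg = np.linspace(10.0, 98.2, 12)
        c = c_mg * 1e-3
        fit = mc.fit_virial(make_series(c_mg, 1 / 193.25 + 2 * 8e-3 * c + 3 * 0.05 * c**2))

        def pressure(ch):  # Π(c) by quadrature of the derivative
            return quad(lambda x: mc.osmotic_pressure_derivative(fit, x), 1e-4, ch,
                        epsrel=1e-12)[0]

        c0, h = 0.05, 1e-5
        fd = (pressure(c0 + h) - pressure(c0 - h)) / (2 * h)
        assert fd == pytest.approx(mc.osmotic_pressure_derivative(fit, c0), rel=1e-6)

    def test_rejects_nonpositive_concentration(self):
        fit = mc.fit_virial(make_series(np.linspace(5, 90, 8), np.full(8, 1e-5)))
        with pytest.raises(InvalidArgumentError):
            mc.osmotic_pressure_derivative(fit, 0.0)


class TestFreeEnergyExcess:
    @staticmethod
    def _fit(mw=193.25, a2=8e-3, a3=0.05):
        c_mg = np.linspace(10.0, 98.2, 12)
        c = c_mg * 1e-3
        return mc.fit_virial(make_series(c_mg, 1 / mw + 2 * a2 * c + 3 * a3 * c**2))

    def test_empty_interval_is_zero(self):
        assert mc.free_energy_excess(self._fit(), 0.03, 0.03, 193.25) == 0.0

    def test_ideal_limit_is_dilute_chemical_potential(self):
        # With A2 = A3 = 0 and Mw equal to the molar mass, Δg = k_BT ln(c_H/c_L).
        from scipy.constants import Boltzmann

        fit = self._fit(a2=0.0, a3=0.0)
        dg = mc.free_energy_excess(fit, 0.02, 0.08, fit.Mw_app)
        kT = Boltzmann * fit.temperature
        assert dg == pytest.approx(kT * np.log(4.0), rel=1e-6)

    @given(st.integers(0, 200))
    def test_quadrature_matches_closed_form(self, draw):
        rng = np.random.default_rng(draw)
        fit = self._fit(
            mw=float(rng.uniform(150, 5e4)),
            a2=float(rng.uniform(0, 2e-2)),
            a3=float(rng.uniform(0, 0.2)),
        )
        c_l = float(rng.uniform(0.011, 0.04))
        c_h = float(rng.uniform(c_l, 0.098))
        a = mc.free_energy_excess(fit, c_l, c_h, 193.25, method="closed_form")
        b = mc.free_energy_excess(fit, c_l, c_h, 193.25, method="quad")
        assert b == pytest.approx(a, rel=1e-8)

    def test_monotone_increasing_in_upper_concentration(self):
        fit = self._fit()
        curve = mc.free_energy_curve(fit, np.linspace(0.012, 0.098, 40), 0.012, 193.25)
        assert np.all(np.diff(curve.dg) > 0)
        assert curve.dg[0] == 0.0
        assert np.all(np.isfinite(curve.dg_kBT))

    def test_ordering_and_divergence_signals(self):
        fit = self._fit()
        with pytest.raises(InvalidArgumentError):
            mc.free_energy_excess(fit, 0.08, 0.02, 193.25)
        with pytest.raises(InvalidArgumentError):
            mc.free_energy_excess(fit, 0.0, 0.02, 193.25)
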
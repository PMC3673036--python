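"""Thermal unfolding: forward model, van't Hoff fits, DSF Tm and ΔTm."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from charkit import (MeltCurve, NoTransitionError, ThermalParams, delta_tm,
                     dsf_tm, fit_thermal, fraction_unfolded, thermal_model)
from charkit.constants import R_GAS


def _f_closed_form(T, tm, dhm):
    """Independent oracle: fraction unfolded via plain math.exp."""
    TK, TmK = T + 273.15, tm + 273.15
    K = math.exp(-dhm * 1e3 * (1.0 - TK / TmK) / (R_GAS * TK))
    return K / (1.0 + K)


def _width_by_bisection(tm, dhm):
    """10–90% transition width (°C) located by bisection on the oracle."""
    lo, hi = tm - 60.0, tm + 60.0
    t10 = brentq(lambda T: _f_closed_form(T, tm, dhm) - 0.1, lo, tm)
    t90 = brentq(lambda T: _f_closed_form(T, tm, dhm) - 0.9, tm, hi)
    return t90 - t10


class TestThermalModel:
    def test_midpoint_is_half(self, temp_grid):
        p = ThermalParams(tm=59.7, dhm=156.6, a_n=1.0, b_n=0.0, a_u=0.0, b_u=0.0)
        assert thermal_model(np.array([59.7]), p)[0] == pytest.approx(0.5, abs=1e-12)

    def test_folded_baseline_limit(self):
        p = ThermalParams(tm=59.7, dhm=156.6, a_n=1.0, b_n=0.01, a_u=0.0, b_u=0.0)
        T = np.array([0.0, 5.0])
        np.testing.assert_allclose(thermal_model(T, p), p.a_n + p.b_n * T, atol=1e-4)

    def test_unfolded_baseline_limit(self):
        p = ThermalParams(tm=45.0, dhm=106.2, a_n=1.0, b_n=0.0, a_u=0.2, b_u=-0.001)
        T = np.array([160.0, 180.0])
        np.testing.assert_allclose(thermal_model(T, p), p.a_u + p.b_u * T, atol=1e-4)

    def test_lower_enthalpy_broadens_transition(self):
        # EphB3-like (106.2 kJ/mol) vs EphB1-like (156.6 kJ/mol)
        assert _width_by_bisection(45.0, 106.2) > _width_by_bisection(59.7, 156.6)

    def test_matches_independent_oracle(self):
        for T in (30.0, 50.0, 59.7, 70.0):
            assert fraction_unfolded(np.array([T]), 59.7, 156.6)[0] == pytest.approx(
                _f_closed_form(T, 59.7, 156.6), rel=1e-12)

    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(ValueError):
            ThermalParams(tm=np.nan, dhm=100.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(tm=st.floats(30.0, 70.0), dhm=st.floats(50.0, 400.0))
    def test_midpoint_property(self, tm, dhm):
        assert abs(fraction_unfolded(np.array([tm]), tm, dhm)[0] - 0.5) < 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(tm=st.floats(30.0, 70.0), dhm=st.floats(50.0, 400.0))
    def test_monotone_in_temperature(self, tm, dhm):
        T = np.linspace(tm - 30, tm + 30, 200)
        f = fraction_unfolded(T, tm, dhm)
        assert np.all(np.diff(f) > 0)


class TestFitThermal:
    def test_noise_free_recovery_at_published_truth(self, clean_melt):
        res = fit_thermal(clean_melt)
        assert res.converged
        assert res.tm == pytest.approx(59.7, rel=1e-3)
        assert res.dhm == pytest.approx(156.6, rel=1e-3)

    def test_roundtrip_random_parameter_sets(self, temp_grid):
        rng = np.random.default_rng(42)
        for _ in range(50):
            truth = ThermalParams(
                tm=rng.uniform(42.8, 59.7),
                dhm=rng.uniform(106.2, 156.6),
                a_n=rng.uniform(0.9, 1.1),
                b_n=rng.uniform(-0.004, -0.002),
                a_u=rng.uniform(0.05, 0.15),
                b_u=rng.uniform(0.001, 0.003),
            )
            curve = MeltCurve(temp_grid, thermal_model(temp_grid, truth))
            res = fit_thermal(curve)
            for name in ("tm", "dhm", "a_n", "b_n", "a_u", "b_u"):
                est, true = getattr(res.params, name), getattr(truth, name)
                assert est == pytest.approx(true, rel=1e-3), name

    def test_mean_tm_unbiased_under_noise(self, ephb1_thermal_params, temp_grid):
        clean = thermal_model(temp_grid, ephb1_thermal_params)
        tms = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = clean + 0.01 * rng.standard_normal(clean.size)
            tms.append(fit_thermal(MeltCurve(temp_grid, noisy)).tm)
        assert abs(np.mean(tms) - 59.7) < 0.2

    def test_flat_line_raises(self, temp_grid):
        with pytest.raises(NoTransitionError):
            fit_thermal(MeltCurve(temp_grid, np.full(temp_grid.size, 0.7)))

    def test_scale_equivariance(self, ephb1_thermal_params, temp_grid):
        y = thermal_model(temp_grid, ephb1_thermal_params)
        r1 = fit_thermal(MeltCurve(temp_grid, y))
        r2 = fit_thermal(MeltCurve(temp_grid, 37.5 * y))
        assert r2.tm == pytest.approx(r1.tm, abs=1e-6)
        assert r2.dhm == pytest.approx(r1.dhm, rel=1e-6)

    def test_standard_errors_positive_under_noise(self, ephb1_thermal_params,
                                                  temp_grid):
        rng = np.random.default_rng(0)
        y = thermal_model(temp_grid, ephb1_thermal_params)
        y += 0.01 * rng.standard_normal(y.size)
        res = fit_thermal(MeltCurve(temp_grid, y))
        assert res.bse["tm"] > 0 and res.bse["dhm"] > 0
        assert res.nobs == temp_grid.size


class TestDSF:
    def _boltzmann(self, T, tm, width, lo=0.1, hi=1.0):
        return lo + (hi - lo) / (1.0 + np.exp((tm - T) / width))

    def test_exact_inflection_recovery(self, temp_grid):
        y = self._boltzmann(temp_grid, 50.0, 2.5)
        curve = MeltCurve(temp_grid, y, modality="DSF")
        assert dsf_tm(curve) == pytest.approx(50.0, abs=1e-6)

    def test_vant_hoff_shape_within_half_degree(self, temp_grid):
        # DSF trace generated from the melt-equilibrium shape at the
        # EphB2 midpoint; the Boltzmann inflection should land within
        # 0.5 °C despite the model mismatch
        p = ThermalParams(tm=53.9, dhm=154.2, a_n=0.1, b_n=0.0, a_u=1.0, b_u=0.0)
        curve = MeltCurve(temp_grid, thermal_model(temp_grid, p), modality="DSF")
        assert dsf_tm(curve) == pytest.approx(53.9, abs=0.5)

    def test_monotone_decreasing_trace_rejected(self, temp_grid):
        y = 1.0 - 0.01 * (temp_grid - 20.0)
        with pytest.raises(NoTransitionError):
            dsf_tm(MeltCurve(temp_grid, y, modality="DSF"))

    def test_cd_modality_rejected(self, clean_melt):
        with pytest.raises(ValueError):
            dsf_tm(clean_melt)


class TestDeltaTm:
    def test_identical_curves_give_zero(self, temp_grid):
        p = ThermalParams(tm=45.0, dhm=106.2, a_n=0.1, b_n=0.0, a_u=1.0, b_u=0.0)
        c = MeltCurve(temp_grid, thermal_model(temp_grid, p), modality="DSF")
        assert delta_tm(c, c) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("shift", [5.0, 2.0])
    def test_constructed_shift_recovered(self, temp_grid, shift):
        apo_p = ThermalParams(tm=45.0, dhm=106.2, a_n=0.1, b_n=0.0, a_u=1.0, b_u=0.0)
        holo_p = ThermalParams(tm=45.0 + shift, dhm=106.2,
                               a_n=0.1, b_n=0.0, a_u=1.0, b_u=0.0)
        apo = MeltCurve(temp_grid, thermal_model(temp_grid, apo_p), modality="DSF")
        holo = MeltCurve(temp_grid, thermal_model(temp_grid, holo_p), modality="DSF")
        assert delta_tm(apo, holo) == pytest.approx(shift, abs=0.1)

    def test_mixed_modalities_rejected(self, temp_grid, clean_melt):
        p = ThermalParams(tm=45.0, dhm=106.2, a_n=0.1, b_n=0.0, a_u=1.0, b_u=0.0)
        dsf = MeltCurve(temp_grid, thermal_model(temp_grid, p), modality="DSF")
        with pytest.raises(ValueError):
            delta_tm(clean_melt, dsf)
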
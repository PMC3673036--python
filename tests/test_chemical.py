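"""Chemical unfolding: LEM models, three-state populations, fits, AICc."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from charkit import (ChemParams2, ChemParams3, DenaturationCurve,
                     compare_models, fit_chemical, pool_replicates,
                     three_state_model, three_state_populations,
                     two_state_model)
from charkit.chemical import aicc
from charkit.constants import R_GAS, T_CHEM


class TestTwoStateModel:
    def test_midpoint_at_cm(self):
        p = ChemParams2(dg_h2o=20.0, m_value=10.0, a_n=1.0, b_n=0.0,
                        a_u=0.0, b_u=0.0)
        assert p.cm == pytest.approx(2.0)
        assert two_state_model(np.array([2.0]), p)[0] == pytest.approx(0.5, abs=1e-12)

    def test_fraction_unfolded_at_zero_denaturant(self):
        # closed form: f(0) = 1/(1+exp(dG/RT))
        p = ChemParams2(dg_h2o=20.0, m_value=10.0, a_n=0.0, b_n=0.0,
                        a_u=1.0, b_u=0.0)
        expected = 1.0 / (1.0 + math.exp(20000.0 / (R_GAS * T_CHEM)))
        assert two_state_model(np.array([0.0]), p)[0] == pytest.approx(expected,
                                                                       rel=1e-9)
        assert expected == pytest.approx(3.1e-4, rel=0.02)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ChemParams2(dg_h2o=np.inf, m_value=10.0)


class TestThreeStateModel:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(dg1=st.floats(-50, 60), m1=st.floats(0.5, 30),
           dg2=st.floats(-50, 80), m2=st.floats(0.5, 30),
           d=st.floats(0.0, 6.0))
    def test_population_conservation(self, dg1, m1, dg2, m2, d):
        pN, pI, pU = three_state_populations(np.array([d]), dg1, m1, dg2, m2)
        assert pN[0] + pI[0] + pU[0] == pytest.approx(1.0, abs=1e-12)

    def test_reduces_to_two_state_when_intermediate_never_forms(self, gdn_grid):
        # K1 → ∞ with z=1: the N↔I step is exhausted and I carries the
        # native amplitude, so N+I↔U behaves two-state in (dg2, m2)
        p3 = ChemParams3(dg1=-60.0, m1=0.1, dg2=20.0, m2=10.0,
                         a_n=1.0, b_n=-0.01, a_u=0.1, b_u=0.0, z_i=1.0)
        p2 = ChemParams2(dg_h2o=20.0, m_value=10.0, a_n=1.0, b_n=-0.01,
                         a_u=0.1, b_u=0.0)
        np.testing.assert_allclose(three_state_model(gdn_grid, p3),
                                   two_state_model(gdn_grid, p2), atol=1e-6)

    def test_native_looking_intermediate_limit(self, gdn_grid):
        # K2 → 0 with z=0: N↔I in (dg1, m1) with a dark intermediate,
        # i.e. a two-state curve with zeroed unfolded baseline
        p3 = ChemParams3(dg1=15.0, m1=12.0, dg2=150.0, m2=0.1,
                         a_n=1.0, b_n=0.0, a_u=0.7, b_u=0.0, z_i=0.0)
        p2 = ChemParams2(dg_h2o=15.0, m_value=12.0, a_n=1.0, b_n=0.0,
                         a_u=0.0, b_u=0.0)
        np.testing.assert_allclose(three_state_model(gdn_grid, p3),
                                   two_state_model(gdn_grid, p2), atol=1e-8)

    def test_intermediate_peaks_at_constructed_midpoint(self):
        # equal m-values put the pI maximum where K1·K2 = 1:
        # D* = (dg1+dg2)/(m1+m2) = 48/24 = 2.0 M
        D = np.linspace(0.0, 6.0, 6001)
        _, pI, _ = three_state_populations(D, 18.0, 12.0, 30.0, 12.0)
        assert D[np.argmax(pI)] == pytest.approx(2.0, abs=0.05)


class TestFitChemical:
    def test_two_state_roundtrip(self, clean_two_state, two_state_params):
        res = fit_chemical(clean_two_state, "two")
        assert res.converged
        assert res.params.dg_h2o == pytest.approx(two_state_params.dg_h2o, rel=1e-3)
        assert res.params.m_value == pytest.approx(two_state_params.m_value, rel=1e-3)

    def test_three_state_roundtrip(self, clean_three_state, three_state_params):
        res = fit_chemical(clean_three_state, "three")
        assert res.converged
        for name in ("dg1", "m1", "dg2", "m2", "a_n", "a_u", "z_i"):
            est = getattr(res.params, name)
            true = getattr(three_state_params, name)
            assert est == pytest.approx(true, rel=1e-3, abs=1e-4), name

    def test_nesting_on_two_state_data(self, clean_two_state):
        rng = np.random.default_rng(5)
        noisy = DenaturationCurve(
            clean_two_state.denaturant,
            clean_two_state.fluorescence + 0.005 * rng.standard_normal(
                len(clean_two_state)),
        )
        f2 = fit_chemical(noisy, "two")
        f3 = fit_chemical(noisy, "three")
        assert f3.rss <= f2.rss * (1.0 + 1e-6) + 1e-12

    def test_unknown_model_name(self, clean_two_state):
        with pytest.raises(ValueError):
            fit_chemical(clean_two_state, "four")

    def test_outlier_diagnostic_flags_signal_collapse(self, clean_two_state):
        # mimic the anomalous transient fluorescence loss near 1 M
        y = clean_two_state.fluorescence.copy()
        idx = np.argmin(np.abs(clean_two_state.denaturant - 1.0))
        y[idx] *= 0.05
        rng = np.random.default_rng(2)
        y += 0.004 * rng.standard_normal(y.size)
        res = fit_chemical(DenaturationCurve(clean_two_state.denaturant, y), "two")
        mask = res.outlier_mask()
        assert mask[idx]

    def test_pool_replicates_averages(self, gdn_grid, two_state_params):
        y = two_state_model(gdn_grid, two_state_params)
        c1 = DenaturationCurve(gdn_grid, y + 0.1, sample_id="s")
        c2 = DenaturationCurve(gdn_grid, y - 0.1, sample_id="s")
        pooled = pool_replicates([c1, c2])
        np.testing.assert_allclose(pooled.fluorescence, y, atol=1e-12)


class TestModelComparison:
    def test_equal_fits_split_evenly(self):
        from types import SimpleNamespace

        # symmetric case: identical RSS and identical k → 50/50
        f2 = SimpleNamespace(n_states=2, nobs=61, rss=0.5, k_free=6)
        f3 = SimpleNamespace(n_states=3, nobs=61, rss=0.5, k_free=6)
        comp = compare_models(f2, f3)
        assert comp.prob_two == pytest.approx(50.0, abs=1e-9)
        assert comp.prob_three == pytest.approx(50.0, abs=1e-9)

    def test_delta_aicc_ten_weight(self):
        # ΔAICc = 10 → weight 1/(1+exp(−5))
        w3 = 100.0 / (1.0 + math.exp(-5.0))
        assert w3 == pytest.approx(99.33, abs=0.01)

    def test_probabilities_sum_to_hundred(self, clean_three_state):
        rng = np.random.default_rng(3)
        noisy = DenaturationCurve(
            clean_three_state.denaturant,
            clean_three_state.fluorescence + 0.005 * rng.standard_normal(
                len(clean_three_state)),
        )
        comp = compare_models(fit_chemical(noisy, "two"),
                              fit_chemical(noisy, "three"))
        assert comp.prob_two + comp.prob_three == pytest.approx(100.0, abs=1e-9)
        assert (comp.aicc_three < comp.aicc_two) == (comp.prob_three > comp.prob_two)

    def test_three_state_data_strongly_selects_three_state(self, clean_three_state):
        rng = np.random.default_rng(7)
        noisy = DenaturationCurve(
            clean_three_state.denaturant,
            clean_three_state.fluorescence + 0.005 * rng.standard_normal(
                len(clean_three_state)),
        )
        comp = compare_models(fit_chemical(noisy, "two"),
                              fit_chemical(noisy, "three"))
        assert comp.prob_three >= 99.99
        assert comp.preferred == "three-state"

    def test_aicc_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            aicc(1.0, 10, 8)  # n − k − 1 = 0

    def test_mismatched_n_rejected(self, clean_two_state, gdn_grid):
        short = DenaturationCurve(gdn_grid[:31],
                                  clean_two_state.fluorescence[:31])
        f2 = fit_chemical(clean_two_state, "two")
        f3 = fit_chemical(short, "three")
        with pytest.raises(ValueError):
            compare_models(f2, f3)
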
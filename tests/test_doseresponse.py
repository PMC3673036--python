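"""Dose-response profiling: dosing scheme, normalization, 4PL IC50 fits."""

import numpy as np
import pytest

from charkit import (DoseResponse, dose_series, fit_ic50, four_param_logistic,
                     normalize, selectivity_report)
from charkit.data import DoseResponsePlate
from charkit.presets import IC50_TABLE


def _make_plate(ic50=0.062, hill=1.0, top_dose=100.0, noise_cv=0.0, seed=0,
                max_level=20000.0, min_level=1000.0):
    rng = np.random.default_rng(seed)
    conc = dose_series(top_dose)
    inh = four_param_logistic(conc, ic50, hill, 100.0, 0.0)
    span = max_level - min_level
    wells = max_level - span * inh / 100.0
    maxc = np.full(11, max_level)
    minc = np.full(11, min_level)
    if noise_cv > 0:
        wells = wells * (1.0 + noise_cv * rng.standard_normal(wells.size))
        maxc = maxc * (1.0 + noise_cv * rng.standard_normal(maxc.size))
        minc = minc * (1.0 + noise_cv * rng.standard_normal(minc.size))
    return DoseResponsePlate("CMPD", "Enz", conc, wells, maxc, minc)


class TestDoseSeries:
    def test_closed_form_points(self):
        c = dose_series(100.0)
        assert c[0] == pytest.approx(100.0)
        assert c[1] == pytest.approx(31.6228, abs=1e-3)
        assert c[10] == pytest.approx(1e-3, rel=1e-9)
        assert c[11] == pytest.approx(1e-4, rel=1e-9)

    def test_half_log_ratio_exact(self):
        c = dose_series(7.0)
        np.testing.assert_allclose(c[:-2] / c[1:-1], np.sqrt(10.0), rtol=1e-12)
        assert c[10] / c[11] == pytest.approx(10.0, rel=1e-12)

    def test_unit_top(self):
        assert dose_series(1.0)[0] == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            dose_series(0.0)


class TestNormalize:
    def test_control_anchors(self):
        plate = _make_plate()
        mean_max = plate.max_controls.mean()
        mean_min = plate.min_controls.mean()
        plate2 = DoseResponsePlate(
            "c", "e", plate.concentrations,
            np.array([mean_max, mean_min, (mean_max + mean_min) / 2] + [mean_max] * 9),
            plate.max_controls, plate.min_controls)
        inh = normalize(plate2)[0]
        assert inh[0] == pytest.approx(0.0, abs=1e-9)
        assert inh[1] == pytest.approx(100.0, abs=1e-9)
        assert inh[2] == pytest.approx(50.0, abs=1e-9)

    def test_idempotent_with_unit_controls(self):
        # once on the percent scale with 0/100 anchor controls,
        # normalization is the identity (signals interpreted as 100−inh)
        plate = _make_plate()
        inh = normalize(plate)
        plate_pct = DoseResponsePlate("c", "e", plate.concentrations,
                                      100.0 - inh, np.array([100.0]),
                                      np.array([0.0]))
        np.testing.assert_allclose(normalize(plate_pct), inh, atol=1e-12)

    def test_degenerate_controls_rejected(self):
        plate = _make_plate()
        bad = DoseResponsePlate("c", "e", plate.concentrations, plate.raw_signal,
                                np.array([5.0]), np.array([10.0]))
        with pytest.raises(ValueError, match="degenerate"):
            normalize(bad)


class TestFourParamLogistic:
    def test_midpoint_at_ic50(self):
        assert four_param_logistic(np.array([0.3]), 0.3, 1.0, 100.0, 0.0)[0] == \
            pytest.approx(50.0, abs=1e-12)

    def test_monotone_for_positive_hill(self):
        c = np.geomspace(1e-4, 100, 500)
        for hill in (0.5, 1.0, 3.0):
            y = four_param_logistic(c, 0.5, hill, 100.0, 0.0)
            assert np.all(np.diff(y) > 0)


class TestIC50Fit:
    def test_noise_free_recovery_at_published_truth(self):
        plate = _make_plate(ic50=0.062)
        res = DoseResponse.from_plate(plate).fit()
        assert res.ic50 == pytest.approx(0.062, rel=1e-3)
        assert res.hill == pytest.approx(1.0, rel=1e-3)
        assert not res.censored

    def test_rescaling_invariance(self):
        plate = _make_plate(ic50=0.5, noise_cv=0.03, seed=4)
        scaled = DoseResponsePlate(plate.compound, plate.enzyme,
                                   plate.concentrations, plate.raw_signal * 7.3,
                                   plate.max_controls * 7.3,
                                   plate.min_controls * 7.3)
        r1 = DoseResponse.from_plate(plate).fit()
        r2 = DoseResponse.from_plate(scaled).fit()
        assert r2.ic50 == pytest.approx(r1.ic50, rel=1e-9)

    def test_weak_inhibitor_reported_as_bound(self):
        res = DoseResponse.from_plate(_make_plate(ic50=1000.0, noise_cv=0.03,
                                                  seed=1)).fit()
        assert res.censored
        assert res.bound == "> 100"
        with pytest.raises(RuntimeError):
            _ = res.value

    def test_tight_binding_flagged(self):
        res = DoseResponse.from_plate(_make_plate(ic50=0.01)).fit()
        assert res.tight_binding

    def test_noisy_median_recovery(self):
        vals = [DoseResponse.from_plate(
            _make_plate(ic50=0.062, noise_cv=0.03, seed=s)).fit().ic50
            for s in range(60)]
        med = float(np.median(vals))
        assert abs(med - 0.062) / 0.062 < 0.15

    def test_rsquared_near_one_on_clean_data(self):
        res = DoseResponse.from_plate(_make_plate(ic50=0.5)).fit()
        assert res.rsquared > 0.9999


class TestSelectivity:
    def test_published_cmpd1_window(self):
        vals = {e: v for e, (v, _) in IC50_TABLE["CMPD1"].items()}
        report = selectivity_report({"CMPD1": vals})
        row = report.set_index("enzyme")
        assert row.loc["EphB3", "fold_vs_best"] == pytest.approx(4.958 / 0.062,
                                                                 rel=1e-6)
        assert row.loc["EphB3", "fold_vs_best"] == pytest.approx(80.0, rel=0.01)

    def test_published_cmpd3_near_equipotent(self):
        vals = {e: v for e, (v, _) in IC50_TABLE["CMPD3"].items()}
        report = selectivity_report({"CMPD3": vals})
        assert report["fold_vs_best"].max() == pytest.approx(0.036 / 0.017,
                                                             rel=1e-6)
        assert report["fold_vs_best"].max() < 2.5

    def test_identical_ic50s_give_unit_ratios(self):
        report = selectivity_report({"X": {"a": 1.0, "b": 1.0}})
        assert (report["fold_vs_best"] == 1.0).all()

    def test_censored_fit_propagates_as_lower_bound(self):
        res = DoseResponse.from_plate(_make_plate(ic50=1000.0)).fit()
        good = DoseResponse.from_plate(_make_plate(ic50=0.1)).fit()
        report = selectivity_report({"X": {"weak": res, "strong": good}})
        row = report.set_index("enzyme")
        assert bool(row.loc["weak", "is_lower_bound"])
        assert row.loc["weak", "fold_vs_best"] > 1.0
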
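"""Plate normalization, 4PL fitting, censored IC50, Bliss enhancement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kinoscope as ks
from kinoscope.errors import ParameterError, ValidationError
from kinoscope.viability import NOT_REACHED, FitResult, four_pl, ic50_from_fit


def plate_from(doses, viabilities, blank=0.1, vehicle=1.1, n_rep=1, drug="d"):
    rows = []
    for r in range(max(n_rep, 1)):
        rows.append(("b", drug, 0.0, "nM", r, blank, "blank"))
        rows.append(("v", drug, 0.0, "nM", r, vehicle, "vehicle"))
    for dose, v in zip(doses, viabilities):
        for r in range(n_rep):
            rows.append(("w", drug, dose, "nM", r, blank + (vehicle - blank) * v, "treated"))
    return pd.DataFrame(rows, columns=["well", "drug", "dose", "unit", "replicate",
                                       "absorbance", "role"])


class TestNormalizePlate:
    def test_viability_arithmetic(self):
        dr = ks.normalize_plate(plate_from([10.0], [0.5]))
        assert dr.mean_viability()[10.0] == pytest.approx(0.5)

    def test_well_at_vehicle_level_is_one(self):
        dr = ks.normalize_plate(plate_from([10.0], [1.0]))
        assert dr.mean_viability()[10.0] == pytest.approx(1.0)

    def test_well_below_blank_retained_with_warning(self):
        plate = plate_from([10.0], [0.5])
        plate.loc[plate["role"] == "treated", "absorbance"] = 0.05  # below blank 0.1
        with pytest.warns(UserWarning, match="negative viabilities"):
            dr = ks.normalize_plate(plate)
        assert dr.mean_viability()[10.0] < 0

    def test_vehicle_not_above_blank_rejected(self):
        with pytest.raises(ValidationError, match="uninterpretable"):
            ks.normalize_plate(plate_from([10.0], [0.5], blank=1.0, vehicle=0.9))

    def test_replicates_not_preaveraged(self):
        dr = ks.normalize_plate(plate_from([10.0], [0.5], n_rep=4))
        assert (dr.viabilities.groupby("dose").size() == 4).all()


class TestFit4PL:
    @pytest.mark.parametrize("params", [
        (0.0, 1.0, 100.0, 1.0),
        (0.25, 1.0, 100.0, 1.0),
        (0.60, 1.0, 300.0, 1.2),
        (0.1, 0.95, 40.0, 2.0),
    ])
    def test_noiseless_roundtrip_recovers_ec50(self, params):
        lower, upper, ec50, hill = params
        doses = np.array(ks.DASATINIB_DOSES_NM)
        v = four_pl(doses, *params)
        fit = ks.fit_4pl(ks.DoseResponse(
            drug="d", doses=doses,
            viabilities=pd.DataFrame({"dose": doses, "replicate": 0, "viability": v}),
        ))
        assert fit.converged
        assert fit.ec50 == pytest.approx(ec50, rel=0.01)

    def test_shoulder_curve_crosses_half_at_double_ec50(self):
        """lower=0.25, upper=1, hill=1, ec50=100: solving 0.5 = 0.25 +
        0.75/(1 + c/100) gives c = 200 exactly."""
        doses = np.array([10.0, 50.0, 100.0, 500.0, 2000.0, 5000.0])
        v = four_pl(doses, 0.25, 1.0, 100.0, 1.0)
        fit = ks.fit_4pl(ks.DoseResponse(
            drug="d", doses=doses,
            viabilities=pd.DataFrame({"dose": doses, "replicate": 0, "viability": v}),
        ))
        assert fit.ic50 == pytest.approx(200.0, rel=1e-3)

    def test_flat_plate_degenerate_but_handled(self):
        doses = np.array([1.0, 10.0, 100.0, 1000.0])
        fit = ks.fit_4pl(ks.DoseResponse(
            drug="d", doses=doses,
            viabilities=pd.DataFrame({"dose": doses, "replicate": 0, "viability": 1.0}),
        ))
        assert fit.ic50 is NOT_REACHED
        assert np.allclose(fit.predict(doses), 1.0, atol=0.02)

    def test_too_few_doses_rejected(self):
        doses = np.array([1.0, 10.0, 100.0])
        with pytest.raises(ParameterError, match="4 distinct doses"):
            ks.fit_4pl(ks.DoseResponse(
                drug="d", doses=doses,
                viabilities=pd.DataFrame({"dose": doses, "replicate": 0, "viability": 0.5}),
            ))

    def test_noisy_quadruplicates_recover_ec50(self):
        truth = ks.ViabilityTruth(lower=0.15, upper=1.0, ec50=80.0, hill=1.5,
                                  noise_sd=0.02, seed=12)
        plate = ks.simulate_viability(ks.TBB_DOSES_UM, truth, n_replicates=4, unit="uM")
        fit = ks.fit_4pl(ks.normalize_plate(plate))
        assert fit.ec50 == pytest.approx(80.0, rel=0.10)


class TestIC50:
    def test_high_floor_censors_ic50(self):
        fit = FitResult(lower=0.60, upper=1.0, ec50=300.0, hill=1.2, rss=0, converged=True)
        assert ic50_from_fit(fit, (50.0, 5000.0)) is NOT_REACHED

    def test_symmetric_curve_ic50_equals_ec50(self):
        fit = FitResult(lower=0.0, upper=1.0, ec50=100.0, hill=1.0, rss=0, converged=True)
        assert ic50_from_fit(fit, (10.0, 5000.0)) == pytest.approx(100.0)

    def test_shoulder_curve_analytic_value(self):
        fit = FitResult(lower=0.25, upper=1.0, ec50=100.0, hill=1.0, rss=0, converged=True)
        assert ic50_from_fit(fit, (10.0, 5000.0)) == pytest.approx(200.0)

    def test_crossing_outside_tested_range_censored(self):
        fit = FitResult(lower=0.0, upper=1.0, ec50=100.0, hill=1.0, rss=0, converged=True)
        assert ic50_from_fit(fit, (200.0, 5000.0)) is NOT_REACHED

    @settings(max_examples=200, deadline=None)
    @given(
        lower=st.floats(0.5, 1.0),
        upper_delta=st.floats(0.0, 0.5),
        ec50=st.floats(1.0, 1e4),
        hill=st.floats(0.1, 10.0),
    )
    def test_floor_at_or_above_half_always_censored(self, lower, upper_delta, ec50, hill):
        fit = FitResult(lower=lower, upper=lower + upper_delta, ec50=ec50,
                        hill=hill, rss=0, converged=True)
        assert ic50_from_fit(fit, (1e-3, 1e6)) is NOT_REACHED


class TestCombination:
    def dr(self, doses, via, drug="A"):
        return ks.DoseResponse(
            drug=drug, doses=np.asarray(doses, float),
            viabilities=pd.DataFrame({"dose": doses, "replicate": 0, "viability": via}),
        )

    def test_published_worked_example(self):
        """Mono-A viability 0.80, fixed-B 0.50, combo 0.05: Bliss expectation
        0.40, excess 0.35, enhancement flagged."""
        doses = [500.0, 5000.0]
        res = ks.analyze_combination(
            self.dr(doses, [0.80, 0.80]), 0.50, self.dr(doses, [0.05, 0.05], "combo"),
        )
        assert res.table["bliss_expected"].iloc[0] == pytest.approx(0.40)
        assert res.table["excess"].iloc[0] == pytest.approx(0.35)
        assert res.enhancement_flag
        assert res.statistic == "enhancement (Bliss excess)"

    def test_independence_null_not_flagged(self):
        doses = [10.0, 100.0, 1000.0]
        va = [0.9, 0.6, 0.3]
        vb = 0.5
        combo = [v * vb for v in va]
        res = ks.analyze_combination(self.dr(doses, va), vb, self.dr(doses, combo, "c"))
        assert np.allclose(res.table["excess"], 0.0, atol=1e-12)
        assert not res.enhancement_flag

    def test_neutral_monotherapies(self):
        doses = [10.0, 100.0]
        res = ks.analyze_combination(
            self.dr(doses, [1.0, 1.0]), 1.0, self.dr(doses, [1.0, 1.0], "c"))
        assert (res.table["bliss_expected"] == 1.0).all()

    def test_no_shared_doses_rejected(self):
        with pytest.raises(ValidationError, match="no shared doses"):
            ks.analyze_combination(
                self.dr([10.0, 20.0], [1, 1]), 0.5, self.dr([30.0, 40.0], [1, 1], "c"))

    def test_flag_needs_min_doses_above_threshold(self):
        doses = [10.0, 100.0, 1000.0]
        va = [1.0, 1.0, 1.0]
        combo = [0.5, 0.45, 0.45]  # excess 0.0, 0.05, 0.05 at vb=0.5
        res = ks.analyze_combination(self.dr(doses, va), 0.5,
                                     self.dr(doses, combo, "c"),
                                     excess_threshold=0.1, min_doses=2)
        assert not res.enhancement_flag


class TestDoseGrids:
    def test_printed_monotherapy_grids(self):
        assert ks.DASATINIB_DOSES_NM == (50, 100, 200, 500, 1000, 5000)
        assert ks.TBB_DOSES_UM == (10, 20, 50, 100, 200, 500)
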
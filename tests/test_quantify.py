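"""ESM vs single-marker quantification, content arithmetic, and RCF ranking."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import qams
from qams.calibration import Analyte, CalibrationCurve
from qams.exceptions import (
    DomainError,
    InsufficientDataError,
    PairingError,
    PanelLookupError,
)

from .conftest import equal_slope_panel, standard_batch


def one_sample(areas, sample_id="S1", mass=0.25, volume=25.0, dilution=1.0):
    return qams.SampleMeasurement(
        sample_id=sample_id, group="Raw", mass_g=mass, volume_ml=volume,
        dilution=dilution, areas=areas,
    )


class TestESM:
    def test_roundtrip_off_reference_curve(self, reference_curves):
        curve = reference_curves["GF3"]
        area = qams.predict_area(curve, 500.0)
        sample = one_sample({"GF3": area})
        conc = qams.esm_quantify(sample, reference_curves)
        assert conc["GF3"] == pytest.approx(500.0, rel=1e-9)

    def test_identity_curve(self):
        curves = {"X": CalibrationCurve(Analyte("X"), slope=1.0, intercept=0.0)}
        conc = qams.esm_quantify(one_sample({"X": 42.0}), curves)
        assert conc["X"] == pytest.approx(42.0)

    def test_noiseless_panel_matches_simulator_truth(self, reference_curves):
        models = qams.default_panel()
        truth = {"GF1": 250.0, "GF3": 500.0, "GF8": 410.0}
        areas = {aid: qams.simulate_area(models[aid], c) for aid, c in truth.items()}
        conc = qams.esm_quantify(one_sample(areas), reference_curves)
        for aid, c in truth.items():
            assert conc[aid] == pytest.approx(c, rel=1e-9)

    def test_missing_curve(self, reference_curves):
        with pytest.raises(PanelLookupError):
            qams.esm_quantify(one_sample({"GF9": 100.0}), reference_curves)


class TestQAMS:
    def test_marker_quantifies_itself_like_esm(self, reference_panel,
                                               reference_curves):
        table = qams.build_rcf_table(reference_panel, "GF3", "A")
        sample = one_sample({"GF3": 300.0})
        esm = qams.esm_quantify(sample, reference_curves)
        q = qams.qams_quantify(sample, reference_curves["GF3"], table)
        assert q["GF3"] == pytest.approx(esm["GF3"], rel=1e-12)

    def test_identical_response_analyte_is_exact(self):
        # an analyte sharing the marker's detector response has RCF 1 and
        # QAMS must coincide with ESM on noiseless areas
        model = qams.DetectorModel("GF3", 1.82, -1.67)
        panel = {
            aid: qams.make_calibration_series(model, 1180.4, analyte=Analyte(aid))
            for aid in ("GF3", "TWIN")
        }
        curves = {a: qams.fit_loglog_calibration(s) for a, s in panel.items()}
        table = qams.build_rcf_table(panel, "GF3", "A")
        sample = one_sample({"TWIN": 777.0})
        esm = qams.esm_quantify(sample, curves)
        q = qams.qams_quantify(sample, curves["GF3"], table)
        assert q["TWIN"] == pytest.approx(esm["TWIN"], rel=1e-9)

    def test_equal_slope_unequal_intercept_recovers_truth_exactly(self):
        # with equal slopes C_detected / C is the same at every level, so the
        # averaged method-A RCF inverts the marker readout without error
        panel, models = equal_slope_panel(noise_cv=0.0, seed=0)
        curves = {a: qams.fit_loglog_calibration(s) for a, s in panel.items()}
        table = qams.build_rcf_table(panel, "GF3", "A")
        truth = {aid: 200.0 + 70.0 * i for i, aid in enumerate(models)}
        areas = {aid: qams.simulate_area(models[aid], c) for aid, c in truth.items()}
        q = qams.qams_quantify(one_sample(areas), curves["GF3"], table)
        for aid, c in truth.items():
            assert q[aid] == pytest.approx(c, rel=1e-9)


class TestContentArithmetic:
    def test_reference_scale(self):
        # 500 µg/mL in 25 mL from 0.25 g is 5 % w/w — the marker's typical level
        assert qams.content_percent(500.0, one_sample({})) == pytest.approx(5.0)

    def test_zero_conc(self):
        assert qams.content_percent(0.0, one_sample({})) == 0.0

    def test_linearities(self):
        base = qams.content_percent(100.0, one_sample({}))
        assert qams.content_percent(
            100.0, one_sample({}, dilution=2.0)
        ) == pytest.approx(2 * base)
        assert qams.content_percent(
            100.0, one_sample({}, mass=0.5)
        ) == pytest.approx(base / 2)
        assert qams.content_percent(200.0, one_sample({})) == pytest.approx(2 * base)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            one_sample({}, mass=0.0)
        with pytest.raises(DomainError):
            qams.content_percent(-1.0, one_sample({}))


class TestRelativeError:
    @pytest.mark.parametrize(
        "q, e, expected", [(5.0, 5.0, 0.0), (1.05, 1.0, 5.0), (0.95, 1.0, -5.0)]
    )
    def test_signed_contract(self, q, e, expected):
        assert qams.relative_error(q, e) == pytest.approx(expected)

    def test_literal_definition(self):
        # RE(a, b) is (a - b)/b * 100, not an antisymmetric form
        a, b = 3.7, 2.9
        assert qams.relative_error(a, b) == pytest.approx((a - b) / b * 100.0)

    def test_nonpositive_reference(self):
        with pytest.raises(DomainError):
            qams.relative_error(1.0, 0.0)


class TestRanking:
    def test_degenerate_panel_ties_at_zero(self):
        model = qams.DetectorModel("GF3", 1.82, -1.67)
        panel = {
            aid: qams.make_calibration_series(model, 1180.4, analyte=Analyte(aid))
            for aid in ("GF3", "GF4")
        }
        areas = {
            aid: qams.simulate_area(model, 400.0) for aid in panel
        }
        summary = qams.rank_rcf_methods([one_sample(areas)], panel, "GF3")
        assert (summary["mean_abs_re"] < 1e-9).all()

    def test_marker_only_sample_gives_zero_for_all_methods(self, reference_panel):
        marker_curve = qams.fit_loglog_calibration(reference_panel["GF3"])
        sample = one_sample({"GF3": qams.predict_area(marker_curve, 500.0)})
        summary = qams.rank_rcf_methods([sample], reference_panel, "GF3")
        assert (summary["mean_abs_re"] < 1e-9).all()

    def test_intercept_shift_selects_marker_readout_method(self):
        # the synthetic restatement of the method comparison: equal slopes,
        # unequal intercepts — only method A tracks the response shift
        panel, models = equal_slope_panel(noise_cv=0.0, seed=3)
        samples, _ = standard_batch(models, noise_seed=11, jitter_cv=0.10)
        assert len(samples) == 30
        summary = qams.rank_rcf_methods(samples, panel, "GF3")
        assert summary.attrs["selected"] == "A"
        by_method = summary.set_index("method")["mean_abs_re"]
        assert by_method["A"] <= 1e-6
        assert by_method["F"] > 10.0  # material intercept shifts
        # with equal slopes B degenerates to no correction and ties with F,
        # both far behind A (E can be worse still: a linear response-factor
        # ratio is the wrong model for a power-law detector)
        order = list(summary["method"])
        assert order.index("F") > order.index("A")
        assert by_method["F"] == pytest.approx(by_method["B"], rel=1e-9)

    def test_empty_batch(self, reference_panel):
        with pytest.raises(InsufficientDataError):
            qams.rank_rcf_methods([], reference_panel, "GF3")


class TestRatioToRaw:
    @staticmethod
    def content_frame(rows):
        return pd.DataFrame(
            rows, columns=["sample_id", "analyte_id", "content_qams_pct"]
        )

    def test_identity_and_doubling(self):
        df = self.content_frame(
            [("Raw_01", "GF2", 2.0), ("Raw_01", "GF3", 5.0),
             ("St_01-1", "GF2", 4.0), ("St_01-1", "GF3", 5.0)]
        )
        out = qams.ratio_to_raw(df, {"St_01-1": "Raw_01"})
        by = out.set_index("analyte_id")["ratio"]
        assert by["GF2"] == pytest.approx(2.0)
        assert by["GF3"] == pytest.approx(1.0)

    def test_zero_raw_content_flagged_as_nan(self):
        df = self.content_frame(
            [("Raw_01", "GF2", 0.0), ("St_01-1", "GF2", 1.0)]
        )
        out = qams.ratio_to_raw(df, {"St_01-1": "Raw_01"})
        assert np.isnan(out["ratio"]).all()

    def test_unpaired_sample(self):
        df = self.content_frame([("Raw_01", "GF2", 2.0)])
        with pytest.raises(PairingError):
            qams.ratio_to_raw(df, {"St_09-9": "Raw_01"})


class TestQuantifierEstimator:
    def test_sklearn_surface(self):
        est = qams.QAMSQuantifier(marker="GF3", method="B", rounding=2)
        params = est.get_params()
        assert params == {"marker": "GF3", "method": "B", "rounding": 2}
        assert clone(est).method == "B"

    def test_predict_before_fit(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            qams.QAMSQuantifier().predict([])

    def test_fitted_attributes_and_prediction(self, reference_panel):
        est = qams.QAMSQuantifier(marker="GF3", method="A").fit(reference_panel)
        assert set(est.curves_) == set(reference_panel)
        assert est.rcf_table_.method == "A"
        models = qams.default_panel()
        areas = {"GF3": qams.simulate_area(models["GF3"], 500.0)}
        out = est.predict([one_sample(areas)])
        assert out.loc[0, "content_esm_pct"] == pytest.approx(5.0, rel=1e-9)
        assert out.loc[0, "re_pct"] == pytest.approx(0.0, abs=1e-9)
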
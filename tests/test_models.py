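"""Outcome models: panel construction, GEE/OLS fits, predictions."""

from datetime import timedelta

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from adhkit.models import (
    CD4ChangeModel,
    WeightGainModel,
    build_cd4_table,
    build_weight_panel,
    typical_patient_profile,
)
from adhkit.records import CD4Test, CohortData, VisitEvent, screen_eligibility
from adhkit.simulate import default_config, generate_cohort
from conftest import D0, make_patient, monthly_regimen_dispensing


@pytest.fixture(scope="module")
def fitted_cohort():
    cfg = default_config()
    cfg.n_patients = 400
    cohort, trace = generate_cohort(cfg, seed=11)
    ids = screen_eligibility(cohort).included_ids
    panel, w_excl = build_weight_panel(cohort, ids)
    cd4, c_excl = build_cd4_table(cohort, ids)
    return cohort, ids, panel, cd4


class TestWeightPanel:
    def test_visit_rows_within_window(self, fitted_cohort):
        _, _, panel, _ = fitted_cohort
        assert (panel["day"] > 0).all()
        assert (panel["day"] <= 270).all()

    def test_visit_beyond_270_excluded(self):
        cohort = CohortData()
        cohort.add_patient(make_patient("A"))
        for day in (30, 280):
            cohort.add_visit(VisitEvent("A", D0 + timedelta(days=day),
                                        weight_kg=55.0, selfreport_code=1))
            cohort.add_dispensing(monthly_regimen_dispensing("A", day))
        panel, excl = build_weight_panel(cohort)
        assert list(panel["day"]) == [30]
        assert excl["visit_beyond_window"] == 1

    def test_visit_missing_weight_dropped_and_counted(self):
        cohort = CohortData()
        cohort.add_patient(make_patient("A"))
        for day, w in ((30, 55.0), (60, None), (90, 56.0)):
            cohort.add_visit(VisitEvent("A", D0 + timedelta(days=day),
                                        weight_kg=w, selfreport_code=1))
            cohort.add_dispensing(monthly_regimen_dispensing("A", day))
        panel, excl = build_weight_panel(cohort)
        assert len(panel) == 2
        assert excl["visit_missing_weight"] == 1

    def test_weight_change_is_relative_to_baseline(self, fitted_cohort):
        cohort, _, panel, _ = fitted_cohort
        row = panel.iloc[0]
        rec = cohort.patients[row["patient_id"]]
        visit = next(v for v in cohort.visits[row["patient_id"]]
                     if (v.actual_date - rec.initiation_date).days == row["day"])
        assert row["weight_change"] == pytest.approx(
            visit.weight_kg - rec.baseline_weight_kg)


class TestCD4Table:
    def test_followup_test_selection_nearest_180(self):
        cohort = CohortData()
        cohort.add_patient(make_patient("A"))
        for day in (30, 100, 250):
            cohort.add_visit(VisitEvent("A", D0 + timedelta(days=day),
                                        weight_kg=55.0, selfreport_code=1))
            cohort.add_dispensing(monthly_regimen_dispensing("A", day))
        cohort.add_cd4(CD4Test("A", D0 - timedelta(days=30), 150))
        cohort.add_cd4(CD4Test("A", D0 + timedelta(days=100), 200))
        cohort.add_cd4(CD4Test("A", D0 + timedelta(days=250), 260))
        table, _ = build_cd4_table(cohort)
        # |100-180| = 80 > |250-180| = 70 -> the day-250 test wins
        assert list(table["days_to_test"]) == [250]
        assert table.iloc[0]["cd4_change"] == 110.0

    def test_no_test_in_window_excludes_patient(self):
        cohort = CohortData()
        cohort.add_patient(make_patient("A"))
        cohort.add_visit(VisitEvent("A", D0 + timedelta(days=30),
                                    weight_kg=55.0, selfreport_code=1))
        cohort.add_dispensing(monthly_regimen_dispensing("A", 30))
        cohort.add_cd4(CD4Test("A", D0 - timedelta(days=30), 150))
        cohort.add_cd4(CD4Test("A", D0 + timedelta(days=300), 260))
        table, excl = build_cd4_table(cohort)
        assert table.empty
        assert excl["no_followup_test"] == 1

    def test_test_at_exactly_180_selected(self):
        cohort = CohortData()
        cohort.add_patient(make_patient("A"))
        cohort.add_visit(VisitEvent("A", D0 + timedelta(days=30),
                                    weight_kg=55.0, selfreport_code=1))
        cohort.add_dispensing(monthly_regimen_dispensing("A", 30))
        cohort.add_cd4(CD4Test("A", D0 + timedelta(days=180), 300))
        table, _ = build_cd4_table(cohort)
        assert list(table["days_to_test"]) == [180]


class TestModelFits:
    def test_gee_with_independence_and_singleton_clusters_equals_ols(
            self, fitted_cohort):
        _, _, panel, _ = fitted_cohort
        single = panel.groupby("patient_id", as_index=False).head(1)
        model = WeightGainModel(single, "gap_gt30")
        gee = model.fit(cov_struct="independence")
        ols = smf.ols(model.formula, data=model.frame).fit()
        assert np.allclose(gee.params.values, ols.params.values, atol=1e-6)

    def test_constant_indicator_is_error(self, fitted_cohort):
        _, _, panel, _ = fitted_cohort
        constant = panel[panel["gap_gt30"] == 0]
        with pytest.raises(ValueError, match="single level"):
            WeightGainModel(constant, "gap_gt30")

    def test_unknown_indicator_is_error(self, fitted_cohort):
        _, _, panel, _ = fitted_cohort
        with pytest.raises(ValueError, match="unknown indicator"):
            WeightGainModel(panel, "nonsense")

    def test_selfreport_models_drop_two_level_patients(self, fitted_cohort):
        _, _, panel, _ = fitted_cohort
        res = WeightGainModel(panel, "any_imperfect").fit()
        assert res.exclusions["two_level_scale_rows"] > 0
        kept = set(res.frame["patient_id"])
        two_level = set(panel.loc[panel["selfreport_scale"] == "two_level",
                                  "patient_id"])
        assert not kept & two_level

    def test_bookkeeping_accounts_for_every_patient(self, fitted_cohort):
        cohort, ids, panel, cd4 = fitted_cohort
        res = CD4ChangeModel(cd4, "coverage_band").fit()
        # patients in the CD4 model + patients excluded for a missing
        # window test partition the eligible cohort
        _, excl = build_cd4_table(cohort, ids)
        assert res.n_patients + excl["no_followup_test"] + \
            excl["no_visits_before_test"] + res.exclusions["incomplete_rows"] \
            == len(ids)

    def test_coverage_band_estimates_negative_low_band(self, fitted_cohort):
        _, _, panel, cd4 = fitted_cohort
        wres = WeightGainModel(panel, "coverage_band").fit()
        terms = wres.indicator_terms().set_index("term")
        low = [t for t in terms.index if "<80%" in t][0]
        assert terms.loc[low, "estimate"] < 0
        assert wres.converged


class TestAdjustedPredictions:
    def test_population_mode_equals_mean_of_row_predictions(self, fitted_cohort):
        _, _, panel, _ = fitted_cohort
        res = WeightGainModel(panel, "gap_gt30").fit()
        est, lo, hi = res.predict_population(at={"gap_gt30": 0, "month_bin": 6})
        frame = res.frame.copy()
        frame["gap_gt30"] = 0
        frame["month_bin"] = 6
        per_row = res.results.predict(frame)
        assert est == pytest.approx(float(np.mean(per_row)), abs=1e-8)
        assert lo < est < hi

    def test_typical_profile_prediction_and_gender_contrast(self, fitted_cohort):
        _, _, panel, _ = fitted_cohort
        res = WeightGainModel(panel, "coverage_band").fit()
        prof_f = typical_patient_profile("female", horizon_day=270)
        prof_m = typical_patient_profile("male", horizon_day=270)
        prof_f["coverage_band"] = prof_m["coverage_band"] = "100%"
        est_f, *_ = res.predict_profile(prof_f)
        est_m, *_ = res.predict_profile(prof_m)
        # by linearity the two typical profiles differ only through the
        # gender and baseline-weight terms
        delta = (res.params["C(gender)[T.male]"]
                 + res.params["baseline_weight"] * (57.2 - 52.8))
        assert est_m - est_f == pytest.approx(delta, abs=1e-8)

    def test_missing_covariate_named_in_error(self, fitted_cohort):
        _, _, panel, _ = fitted_cohort
        res = WeightGainModel(panel, "gap_gt30").fit()
        profile = typical_patient_profile("female")
        profile["gap_gt30"] = 0
        del profile["baseline_cd4"]
        with pytest.raises(ValueError, match="baseline_cd4"):
            res.predict_profile(profile)
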
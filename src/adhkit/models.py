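"""Validation models: do the adherence indicators predict clinical change?

Two model families, in statsmodels style (a Model built from data whose
``fit()`` returns a Results object):

* :class:`WeightGainModel` — a marginal (GEE) linear model for weight
  change from baseline at every clinic visit in the first 270 days, with
  the patient as the cluster, an exchangeable working correlation and
  robust (sandwich) standard errors.
* :class:`CD4ChangeModel` — ordinary least squares for the change in CD4
  count between the baseline test and one follow-up test in days 91-270
  (the test closest to day 180; ties to the earlier test).

Each adherence indicator is modeled separately, entered on top of a fixed
covariate set: gender, age band, marital status, clinic location,
baseline CD4, WHO stage (1-2 vs 3-4), TB at initiation, any side effect
or opportunistic infection to date, number of distinct regimens to date,
ever on a protease inhibitor, and time since initiation (30-day month
bins for the weight model, days-to-test for the CD4 model).  The weight
model additionally adjusts for baseline weight.  Patients recorded on
the two-level self-report coding are excluded from self-report indicator
models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices

from .indicators import snapshot_at, categorize_coverage
from .records import CohortData

__all__ = [
    "INDICATORS",
    "build_weight_panel",
    "build_cd4_table",
    "WeightGainModel",
    "CD4ChangeModel",
    "AdherenceResults",
    "typical_patient_profile",
]

#: Indicator encodings available to both model families.  ``term`` is the
#: patsy term; ``needs_selfreport`` marks indicators estimated only on
#: three-level-scale patients; ``source`` names the panel column(s) that
#: must be non-missing.
INDICATORS: dict[str, dict] = {
    "coverage_band": {
        "term": "C(coverage_band, Treatment(reference='100%'))",
        "columns": ["coverage_band"],
        "needs_selfreport": False,
    },
    "gap_gt30": {
        "term": "gap_gt30",
        "columns": ["gap_gt30"],
        "needs_selfreport": False,
    },
    "selfreport_band": {
        "term": "C(selfreport_band, Treatment(reference='all_perfect'))",
        "columns": ["selfreport_band"],
        "needs_selfreport": True,
    },
    "any_imperfect": {
        "term": "any_imperfect",
        "columns": ["any_imperfect"],
        "needs_selfreport": True,
    },
    "lt80_on_schedule": {
        "term": "lt80_on_schedule",
        "columns": ["lt80_on_schedule"],
        "needs_selfreport": False,
    },
    "lt80_within3": {
        "term": "lt80_within3",
        "columns": ["lt80_within3"],
        "needs_selfreport": False,
    },
    "lt80_exhaustion": {
        "term": "lt80_exhaustion",
        "columns": ["lt80_exhaustion"],
        "needs_selfreport": False,
    },
}

_BASE_COVARIATES = (
    "C(gender) + C(age_band) + married + C(location) + baseline_cd4"
    " + who_stage_34 + tb_at_initiation + side_effect_to_date"
    " + n_regimens + ever_pi"
)


def _selfreport_band(avg: float | None) -> str | None:
    if avg is None:
        return None
    if avg == 1.0:
        return "all_perfect"
    if avg < 2.0:
        return "good_to_perfect"
    return "good_or_worse"


def _indicator_fields(snap, rec) -> dict:
    pct = snap.pct_days_covered
    return {
        "coverage_pct": pct,
        "coverage_band": categorize_coverage(pct, "model"),
        "gap_gt30": int(snap.gap_gt30),
        "selfreport_band": _selfreport_band(snap.avg_selfreport),
        "any_imperfect": (None if snap.any_imperfect_selfreport is None
                          else int(snap.any_imperfect_selfreport)),
        "lt80_on_schedule": (None if snap.pct_visits_on_or_before is None
                             else int(snap.pct_visits_on_or_before < 80.0)),
        "lt80_within3": (None if snap.pct_visits_within_3d is None
                         else int(snap.pct_visits_within_3d < 80.0)),
        "lt80_exhaustion": (None if snap.pct_visits_before_exhaustion is None
                            else int(snap.pct_visits_before_exhaustion < 80.0)),
        "selfreport_scale": rec.selfreport_scale,
    }


def _covariate_fields(rec, visits_upto, dispensings_upto) -> dict:
    regimens = {v.regimen_id for v in visits_upto if v.regimen_id}
    return {
        "gender": rec.gender,
        "age_band": rec.age_band,
        "married": int(rec.married),
        "location": rec.location,
        "baseline_cd4": float(rec.baseline_cd4),
        "baseline_weight": rec.baseline_weight_kg,
        "who_stage_34": int(rec.who_stage >= 3),
        "tb_at_initiation": int(rec.tb_at_initiation),
        "side_effect_to_date": int(any(v.side_effect_or_oi_flag for v in visits_upto)),
        "n_regimens": float(len(regimens)) if regimens else 1.0,
        "ever_pi": int(any(d.contains_pi for d in dispensings_upto)),
    }


def build_weight_panel(
    cohort: CohortData,
    patient_ids: list[str] | None = None,
    max_day: int = 270,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """One row per (patient, visit) within the first ``max_day`` days.

    Rows need a recorded visit weight and a patient baseline weight; every
    indicator is evaluated cumulatively as of the visit date.  Returns the
    panel and an exclusion tally (patients without baseline weight, visits
    without weight, day-0 visits, visits beyond the window).
    """
    ids = patient_ids if patient_ids is not None else cohort.patient_ids()
    excl = {"no_baseline_weight": 0, "visit_missing_weight": 0,
            "visit_beyond_window": 0}
    rows = []
    for pid in ids:
        rec = cohort.patients[pid]
        if rec.baseline_weight_kg is None or rec.baseline_weight_kg <= 0:
            excl["no_baseline_weight"] += 1
            continue
        visits = cohort.visits.get(pid, [])
        disps = cohort.dispensings.get(pid, [])
        for v in visits:
            day = (v.actual_date - rec.initiation_date).days
            if day <= 0:
                continue
            if day > max_day:
                excl["visit_beyond_window"] += 1
                continue
            if v.weight_kg is None:
                excl["visit_missing_weight"] += 1
                continue
            snap = snapshot_at(rec, visits, disps, v.actual_date)
            upto_v = [u for u in visits if u.actual_date <= v.actual_date]
            upto_d = [d for d in disps if d.dispense_date <= v.actual_date]
            row = {
                "patient_id": pid,
                "day": day,
                "month_bin": int(np.ceil(day / 30.0)),
                "weight_change": v.weight_kg - rec.baseline_weight_kg,
            }
            row.update(_indicator_fields(snap, rec))
            row.update(_covariate_fields(rec, upto_v, upto_d))
            rows.append(row)
    return pd.DataFrame(rows), excl


def build_cd4_table(
    cohort: CohortData,
    patient_ids: list[str] | None = None,
    window: tuple[int, int] = (91, 270),
    target_day: int = 180,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """One row per patient with a follow-up CD4 test in the day window.

    The follow-up test is the one closest to ``target_day`` (ties to the
    earlier test); indicators are evaluated as of the test date.  Patients
    without a test in the window are excluded from this table only.
    """
    ids = patient_ids if patient_ids is not None else cohort.patient_ids()
    lo, hi = window
    excl = {"no_followup_test": 0, "no_visits_before_test": 0}
    rows = []
    for pid in ids:
        rec = cohort.patients[pid]
        candidates = [
            t for t in cohort.cd4_tests.get(pid, [])
            if lo <= (t.test_date - rec.initiation_date).days <= hi
        ]
        if not candidates:
            excl["no_followup_test"] += 1
            continue
        test = min(
            candidates,
            key=lambda t: (abs((t.test_date - rec.initiation_date).days - target_day),
                           t.test_date),
        )
        visits = cohort.visits.get(pid, [])
        disps = cohort.dispensings.get(pid, [])
        try:
            snap = snapshot_at(rec, visits, disps, test.test_date)
        except ValueError:
            excl["no_visits_before_test"] += 1
            continue
        upto_v = [u for u in visits if u.actual_date <= test.test_date]
        upto_d = [d for d in disps if d.dispense_date <= test.test_date]
        row = {
            "patient_id": pid,
            "days_to_test": (test.test_date - rec.initiation_date).days,
            "cd4_change": float(test.count - rec.baseline_cd4),
        }
        row.update(_indicator_fields(snap, rec))
        row.update(_covariate_fields(rec, upto_v, upto_d))
        del row["baseline_weight"]
        rows.append(row)
    return pd.DataFrame(rows), excl


@dataclass
class AdherenceResults:
    """Estimates for one fitted validation model.

    Wraps the underlying statsmodels results and exposes the indicator
    terms (estimate, 95% CI, p-value), sample bookkeeping, and adjusted
    predictions.
    """

    model_kind: str                 # "gee_weight" | "ols_cd4"
    indicator: str
    formula: str
    results: object                 # statsmodels results instance
    frame: pd.DataFrame             # estimation frame (complete cases)
    n_patients: int
    n_obs: int
    exclusions: dict[str, int] = field(default_factory=dict)

    @property
    def params(self) -> pd.Series:
        return self.results.params

    @property
    def pvalues(self) -> pd.Series:
        return self.results.pvalues

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.results.conf_int(alpha)
        ci.columns = ["ci_low", "ci_high"]
        return ci

    @property
    def converged(self) -> bool:
        return bool(getattr(self.results, "converged", True))

    def indicator_terms(self) -> pd.DataFrame:
        """Rows of the coefficient table belonging to the indicator."""
        col = INDICATORS[self.indicator]["columns"][0]
        names = [n for n in self.params.index if col in n]
        ci = self.conf_int()
        out = pd.DataFrame({
            "term": names,
            "estimate": [self.params[n] for n in names],
            "p_value": [self.pvalues[n] for n in names],
            "ci_low": [ci.loc[n, "ci_low"] for n in names],
            "ci_high": [ci.loc[n, "ci_high"] for n in names],
        })
        out["indicator"] = self.indicator
        out["model"] = self.model_kind
        out["n_patients"] = self.n_patients
        out["n_obs"] = self.n_obs
        return out

    def summary(self):
        return self.results.summary()

    # ---- adjusted predictions --------------------------------------------
    def _design(self, frame: pd.DataFrame) -> np.ndarray:
        design_info = self.results.model.data.design_info
        (X,) = build_design_matrices([design_info], frame, return_type="dataframe")
        return np.asarray(X)

    def _predict_rows(self, frame: pd.DataFrame) -> tuple[float, float, float]:
        X = self._design(frame)
        xbar = X.mean(axis=0)
        est = float(xbar @ np.asarray(self.params))
        cov = np.asarray(self.results.cov_params())
        se = float(np.sqrt(xbar @ cov @ xbar))
        return est, est - 1.96 * se, est + 1.96 * se

    def predict_profile(self, profile: dict) -> tuple[float, float, float]:
        """Typical-patient prediction at a fixed covariate profile.

        Returns (estimate, ci_low, ci_high).  The profile must cover every
        model covariate; a missing one raises a ValueError naming it.
        """
        needed = set(self.frame.columns) - {"weight_change", "cd4_change",
                                            "patient_id", "day", "coverage_pct",
                                            "selfreport_scale"}
        missing = sorted(n for n in needed if n not in profile)
        # columns not referenced by the formula are harmless; check against
        # the formula instead
        missing = [n for n in missing if n in self.formula]
        if missing:
            raise ValueError(f"profile missing covariate(s): {', '.join(missing)}")
        return self._predict_rows(pd.DataFrame([profile]))

    def predict_population(self, at: dict | None = None) -> tuple[float, float, float]:
        """Population-averaged prediction over the estimation frame.

        ``at`` overrides columns (e.g. fix the indicator at one level and
        the time at one horizon) while the remaining covariates keep their
        observed distribution; the result is the mean of the per-row
        predictions.
        """
        frame = self.frame.copy()
        for k, v in (at or {}).items():
            frame[k] = v
        return self._predict_rows(frame)


class _BaseAdherenceModel:
    """Shared formula assembly and complete-case bookkeeping."""

    outcome: str
    model_kind: str
    time_term: str

    def __init__(self, data: pd.DataFrame, indicator: str,
                 exclusions: dict[str, int] | None = None):
        if indicator not in INDICATORS:
            raise ValueError(
                f"unknown indicator {indicator!r}; choose from {sorted(INDICATORS)}")
        self.indicator = indicator
        self.exclusions = dict(exclusions or {})
        spec = INDICATORS[indicator]

        frame = data.copy()
        n0 = len(frame)
        if spec["needs_selfreport"]:
            frame = frame[frame["selfreport_scale"] == "three_level"]
            self.exclusions["two_level_scale_rows"] = n0 - len(frame)
        required = spec["columns"] + self._covariate_columns()
        n1 = len(frame)
        frame = frame.dropna(subset=[c for c in required if c in frame.columns])
        self.exclusions["incomplete_rows"] = n1 - len(frame)
        if frame.empty:
            raise ValueError("no complete-case rows to fit")
        col = spec["columns"][0]
        if frame[col].nunique() < 2:
            raise ValueError(
                f"indicator {indicator!r} takes a single level in the data")
        self.frame = frame.reset_index(drop=True)
        self.formula = (
            f"{self.outcome} ~ {spec['term']} + {_BASE_COVARIATES}"
            f"{self._extra_covariates()} + {self.time_term}"
        )

    def _covariate_columns(self) -> list[str]:
        return ["gender", "age_band", "married", "location", "baseline_cd4",
                "who_stage_34", "tb_at_initiation", "side_effect_to_date",
                "n_regimens", "ever_pi"]

    def _extra_covariates(self) -> str:
        return ""


class WeightGainModel(_BaseAdherenceModel):
    """GEE model of weight change at each visit in the first 270 days.

    Parameters
    ----------
    panel : DataFrame from :func:`build_weight_panel`
    indicator : one of :data:`INDICATORS`
    time_coding : "month_bins" (categorical 30-day bins, default) or
        "linear" (days since initiation as a single slope)
    """

    outcome = "weight_change"
    model_kind = "gee_weight"

    def __init__(self, panel: pd.DataFrame, indicator: str,
                 time_coding: Literal["month_bins", "linear"] = "month_bins",
                 exclusions: dict[str, int] | None = None):
        self.time_term = "C(month_bin)" if time_coding == "month_bins" else "day"
        super().__init__(panel, indicator, exclusions)

    @classmethod
    def from_cohort(cls, cohort: CohortData, indicator: str,
                    patient_ids: list[str] | None = None,
                    **kwargs) -> "WeightGainModel":
        panel, excl = build_weight_panel(cohort, patient_ids)
        return cls(panel, indicator, exclusions=excl, **kwargs)

    def _covariate_columns(self) -> list[str]:
        return super()._covariate_columns() + ["baseline_weight", "weight_change"]

    def _extra_covariates(self) -> str:
        return " + baseline_weight"

    def fit(self, cov_struct: Literal["exchangeable", "independence"] = "exchangeable",
            maxiter: int = 60) -> AdherenceResults:
        struct = (sm.cov_struct.Exchangeable() if cov_struct == "exchangeable"
                  else sm.cov_struct.Independence())
        model = smf.gee(self.formula, groups="patient_id", data=self.frame,
                        cov_struct=struct)
        results = model.fit(maxiter=maxiter)
        if not getattr(results, "converged", True):
            raise RuntimeError(
                f"GEE did not converge for indicator {self.indicator!r}")
        return AdherenceResults(
            model_kind=self.model_kind,
            indicator=self.indicator,
            formula=self.formula,
            results=results,
            frame=self.frame,
            n_patients=self.frame["patient_id"].nunique(),
            n_obs=len(self.frame),
            exclusions=self.exclusions,
        )


class CD4ChangeModel(_BaseAdherenceModel):
    """OLS model of CD4 change at the follow-up test (days 91-270)."""

    outcome = "cd4_change"
    model_kind = "ols_cd4"
    time_term = "days_to_test"

    @classmethod
    def from_cohort(cls, cohort: CohortData, indicator: str,
                    patient_ids: list[str] | None = None) -> "CD4ChangeModel":
        table, excl = build_cd4_table(cohort, patient_ids)
        return cls(table, indicator, exclusions=excl)

    def _covariate_columns(self) -> list[str]:
        return super()._covariate_columns() + ["days_to_test", "cd4_change"]

    def fit(self) -> AdherenceResults:
        results = smf.ols(self.formula, data=self.frame).fit()
        return AdherenceResults(
            model_kind=self.model_kind,
            indicator=self.indicator,
            formula=self.formula,
            results=results,
            frame=self.frame,
            n_patients=self.frame["patient_id"].nunique(),
            n_obs=len(self.frame),
            exclusions=self.exclusions,
        )


def typical_patient_profile(gender: str = "female",
                            horizon_day: int = 270,
                            model_kind: str = "gee_weight") -> dict:
    """The fixed covariate profile used for typical-patient predictions.

    Age 31-40, living in the capital, married, baseline CD4 139.8,
    baseline weight 52.8 kg (women) / 57.2 kg (men), 1.6 regimens on
    average, no side effects or opportunistic infections, never on a
    protease inhibitor, WHO stage 3-4, no TB.
    """
    profile = {
        "gender": gender,
        "age_band": "31-40",
        "married": 1,
        "location": "capital",
        "baseline_cd4": 139.8,
        "who_stage_34": 1,
        "tb_at_initiation": 0,
        "side_effect_to_date": 0,
        "n_regimens": 1.6,
        "ever_pi": 0,
    }
    if model_kind == "gee_weight":
        profile["baseline_weight"] = 52.8 if gender == "female" else 57.2
        profile["month_bin"] = int(np.ceil(horizon_day / 30.0))
        profile["day"] = horizon_day
    else:
        profile["days_to_test"] = horizon_day
    return profile
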
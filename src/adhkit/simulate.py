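"""Seeded synthetic ART cohort generator.

Emulates the event-log structure of routine clinic records from East
African ART programs: an intake record per patient, roughly monthly
clinic visits each carrying a same-day dispensing of ~30 days of
medicines, self-reported adherence codes, weights at every visit, a
baseline CD4 test shortly before initiation and one follow-up test 3-9
months later.

A single latent adherence propensity per patient jointly drives refill
lateness, missed visits, and long treatment interruptions, so that
dispensing-based, self-report, and attendance-based measures come out
positively correlated — the qualitative structure the real analysis
exhibits.  Outcomes (weight trajectory, CD4 gain) depend on the
patient's *true* running medication coverage, so the validation models
downstream have a known truth to recover.

Default parameters are anchored to the observed cohort: demographic
marginals, gender-specific baseline weights, baseline CD4 bands, ~63%
full coverage / ~3% long gaps at six months, a concave weight trajectory
reaching ~3.9 kg by month 6, and a mean CD4 gain near +140 cells/mm3.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .records import (
    CD4Test,
    CohortData,
    DispensingEvent,
    PatientRecord,
    VisitEvent,
)

__all__ = ["CohortConfig", "GenerationTrace", "default_config", "generate_cohort"]

_PROB_TOL = 1e-9

# Component drug codes per regimen, used to populate dispensing rows.
_REGIMENS = {
    "AZT-3TC-NVP": ("AZT", "3TC", "NVP"),
    "d4T-3TC-NVP": ("d4T", "3TC", "NVP"),
    "AZT-3TC-EFV": ("AZT", "3TC", "EFV"),
    "TDF-3TC-LPVr": ("TDF", "3TC", "LPVr"),  # protease-inhibitor regimen
}
_FIRSTLINE = ("AZT-3TC-NVP", "d4T-3TC-NVP", "AZT-3TC-EFV")
_PI_REGIMEN = "TDF-3TC-LPVr"


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _shifted_prob(base: float, shift: float) -> float:
    """Shift a base probability by ``shift`` on the log-odds scale.

    Degenerate bases (0 or 1) are returned unchanged so that configs can
    switch a behavior off (or force it) exactly.
    """
    if base <= 0.0 or base >= 1.0:
        return base
    return _sigmoid(_logit(base) + shift)


@dataclass
class AdherenceBehavior:
    """Behavioral parameters; per-patient values shift with the latent
    propensity on the log-odds scale (higher propensity = better behavior)."""

    propensity_sd: float = 1.0
    prob_perfect_refill: float = 0.95
    #: lateness mixture given a late arrival: day-range -> probability
    refill_delay_distribution: dict[str, float] = field(default_factory=lambda: {
        "1-3": 0.60, "4-7": 0.25, "8-14": 0.10, "15-30": 0.05,
    })
    prob_long_interruption: float = 0.010
    #: interruption = ``min`` + Geometric(1/``mean_excess``) - 1 uncovered
    #: days (capped at ``max``) starting when supply runs out after a
    #: trigger day drawn uniformly in ``start_range``.  Most treatment
    #: interruptions happen early in therapy, hence the early default range.
    interruption_length_distribution: dict[str, Any] = field(default_factory=lambda: {
        "min": 31, "mean_excess": 15, "max": 85, "start_range": (30, 150),
    })
    missed_visit_prob: float = 0.015
    #: probability a true lapse is still self-reported as perfect
    selfreport_optimism: float = 0.8
    #: probability a self-report is recorded at an attended visit
    selfreport_record_prob: float = 0.9


@dataclass
class OutcomeModel:
    """Outcome generation: weight trajectory and CD4 gain vs true coverage."""

    #: kg gained in each 30-day month under full adherence (concave:
    #: fast early gain, plateau by month ~9; cumulative 3.9 kg at month 6)
    monthly_weight_gain_curve: list[float] = field(default_factory=lambda: [
        1.4, 1.0, 0.6, 0.4, 0.3, 0.2, 0.15, 0.10, 0.05,
    ])
    weight_penalty_low_coverage_kg: float = -2.24
    weight_penalty_mid_bands: dict[str, float] = field(default_factory=lambda: {
        "80% to <90%": -0.51, "90% to <100%": -0.52,
    })
    weight_penalty_gap_kg: float = -3.26
    cd4_gain_full_coverage: float = 148.8
    cd4_penalty_low_coverage: float = -97.3
    cd4_penalty_mid_bands: dict[str, float] = field(default_factory=lambda: {
        "80% to <90%": -28.8, "90% to <100%": -22.1,
    })
    #: weight residuals: shared patient intercept + visit noise (kg);
    #: exchangeable within-patient correlation = between^2/(between^2+within^2)
    residual_sds: dict[str, float] = field(default_factory=lambda: {
        "weight_between": 3.0, "weight_within": 3.0, "cd4": 120.0,
    })
    #: follow-up CD4 test drawn uniformly in this day window
    cd4_test_window_days: tuple[int, int] = (91, 270)


@dataclass
class CohortConfig:
    """Full parameterization of the generator.

    Demographic marginals are probability vectors over the categorical
    intake fields; binary fields carry a single probability.  Baseline
    weights are gender-specific (mean, SD) in kg.  ``under_18`` and
    ``prior_art_exposure`` default to zero; raising them deliberately
    injects screen-ineligible patients.
    """

    n_patients: int = 488
    seed: int = 0
    demographic_marginals: dict[str, Any] = field(default_factory=lambda: {
        "gender": {"female": 0.625, "male": 0.375},
        "age_band": {"<=30": 0.293, "31-40": 0.434, ">40": 0.273},
        "education": {"none": 0.155, "primary": 0.467, "secondary+": 0.378},
        "living": {"alone": 0.060, "with_child_only": 0.245, "with_adult": 0.695},
        "occupation": {"employed": 0.283, "self-employed": 0.322, "unemployed": 0.395},
        "facility_management": {"government": 0.635, "other": 0.365},
        "location": {"capital": 0.498, "other_urban": 0.264, "rural": 0.238},
        "who_stage": {"1": 0.089, "2": 0.254, "3": 0.544, "4": 0.113},
        "married": 0.441,
        "support_partner": 0.887,
        "pmtct_female": 0.062,
        "tb_at_initiation": 0.152,
        "prior_art_exposure": 0.0,
        "under_18": 0.0,
        "two_level_scale": 0.25,
    })
    baseline_weight: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "male": (57.2, 9.2), "female": (52.9, 9.7),
    })
    baseline_cd4_band_probs: dict[str, float] = field(default_factory=lambda: {
        "<=100": 0.374, "101-200": 0.404, "201-350": 0.206, "351+": 0.016,
    })
    adherence_model: AdherenceBehavior = field(default_factory=AdherenceBehavior)
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    schedule_interval_days: int = 30
    followup_months: int = 18

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        m = self.demographic_marginals
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        for key in ("gender", "age_band", "education", "living", "occupation",
                    "facility_management", "location", "who_stage"):
            probs = m[key]
            total = sum(probs.values())
            if abs(total - 1.0) > _PROB_TOL:
                raise ValueError(f"marginal {key!r} sums to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"marginal {key!r} has negative probability")
        for key in ("married", "support_partner", "pmtct_female",
                    "tb_at_initiation", "prior_art_exposure", "under_18",
                    "two_level_scale"):
            p = m[key]
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {key!r}={p} outside [0,1]")
        if abs(sum(self.baseline_cd4_band_probs.values()) - 1.0) > _PROB_TOL:
            raise ValueError("baseline_cd4_band_probs must sum to 1")
        for g, (mu, sd) in self.baseline_weight.items():
            if sd <= 0:
                raise ValueError(f"baseline weight SD for {g} must be > 0")
        a = self.adherence_model
        if a.propensity_sd <= 0:
            raise ValueError("propensity_sd must be > 0")
        for p in (a.prob_perfect_refill, a.prob_long_interruption,
                  a.missed_visit_prob, a.selfreport_optimism,
                  a.selfreport_record_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"behavior probability {p} outside [0,1]")
        if abs(sum(a.refill_delay_distribution.values()) - 1.0) > _PROB_TOL:
            raise ValueError("refill_delay_distribution must sum to 1")
        ild = a.interruption_length_distribution
        if ild["min"] < 1 or ild["mean_excess"] < 1 or ild["max"] < ild["min"]:
            raise ValueError("bad interruption_length_distribution")
        o = self.outcome_model
        for v in (o.weight_penalty_low_coverage_kg, o.weight_penalty_gap_kg,
                  o.cd4_gain_full_coverage, o.cd4_penalty_low_coverage):
            if not math.isfinite(v):
                raise ValueError("outcome effect parameters must be finite")
        for sd in o.residual_sds.values():
            if sd <= 0:
                raise ValueError("residual SDs must be > 0")
        lo, hi = o.cd4_test_window_days
        if not (0 < lo < hi):
            raise ValueError("cd4_test_window_days must be an increasing pair")
        if self.schedule_interval_days < 1 or self.followup_months < 1:
            raise ValueError("schedule interval and follow-up must be positive")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["outcome_model"]["cd4_test_window_days"] = list(
            d["outcome_model"]["cd4_test_window_days"])
        ild = d["adherence_model"]["interruption_length_distribution"]
        ild["start_range"] = list(ild["start_range"])
        d["baseline_weight"] = {k: list(v) for k, v in d["baseline_weight"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = copy.deepcopy(d)
        adh = d.pop("adherence_model", {})
        out = d.pop("outcome_model", {})
        if "cd4_test_window_days" in out:
            out["cd4_test_window_days"] = tuple(out["cd4_test_window_days"])
        if "start_range" in adh.get("interruption_length_distribution", {}):
            ild = adh["interruption_length_distribution"]
            ild["start_range"] = tuple(ild["start_range"])
        if "baseline_weight" in d:
            d["baseline_weight"] = {k: tuple(v) for k, v in d["baseline_weight"].items()}
        return cls(**d, adherence_model=AdherenceBehavior(**adh),
                   outcome_model=OutcomeModel(**out))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GenerationTrace:
    """Per-patient latent truth retained for parameter-recovery tests.

    One row per patient: latent propensity, true coverage fraction on the
    simulator's own day grid at day 180 (or end of observation if
    earlier), true long-gap indicators at day 180 and over the whole
    observed window, and whether an interruption was injected.
    """

    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)


def default_config() -> CohortConfig:
    """The default study-condition configuration.

    Anchors: 62.5% female; age bands 29.3/43.4/27.3%; education
    15.5/46.7/37.8%; 44.1% married; government facilities 63.5%; location
    49.8/26.4/23.8%; WHO stages 8.9/25.4/54.4/11.3%; baseline weight
    57.2 (9.2) kg male / 52.9 (9.7) kg female; baseline CD4 bands
    37/40/21/2%; weight curve reaching 3.9 kg at month 6; CD4 gain 148.8
    under full coverage with band penalties -97.3 / -28.8 / -22.1.
    """
    cfg = CohortConfig()
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# generation internals
# ---------------------------------------------------------------------------

def _sample_cat(rng: np.random.Generator, probs: dict[str, float]) -> str:
    keys = list(probs)
    return keys[rng.choice(len(keys), p=np.asarray([probs[k] for k in keys]))]


_AGE_RANGES = {"<=30": (18, 30), "31-40": (31, 40), ">40": (41, 60)}
_CD4_RANGES = {"<=100": (20, 100), "101-200": (101, 200),
               "201-350": (201, 350), "351+": (351, 500)}
_DELAY_RANGES = {"1-3": (1, 3), "4-7": (4, 7), "8-14": (8, 14), "15-30": (15, 30)}


def _daily_coverage(disp: list[tuple[int, int]], upto: int) -> np.ndarray:
    """Per-day supply-pool walk: day d is covered iff the pool (including
    any same-day dispensing) is positive entering day d."""
    by_day: dict[int, int] = {}
    for d, s in disp:
        if 0 <= d < upto:
            by_day[d] = by_day.get(d, 0) + s
    covered = np.zeros(upto, dtype=bool)
    pool = 0
    for day in range(upto):
        pool += by_day.get(day, 0)
        if pool > 0:
            covered[day] = True
            pool -= 1
    return covered


def _prefix_longest_gap(covered: np.ndarray) -> np.ndarray:
    """g[d] = longest uncovered run within covered[:d+1]."""
    g = np.zeros(len(covered), dtype=int)
    best = run = 0
    for d, c in enumerate(covered):
        run = 0 if c else run + 1
        best = max(best, run)
        g[d] = best
    return g


def _weight_curve_at(curve: list[float], day: int) -> float:
    """Cumulative kg gained by ``day`` under full adherence (30-day months,
    linear within months, flat after the curve ends)."""
    months = day / 30.0
    total = 0.0
    for i, gain in enumerate(curve):
        if months >= i + 1:
            total += gain
        elif months > i:
            total += gain * (months - i)
            break
        else:
            break
    return total


def _coverage_band(pct: float) -> str:
    if pct < 80.0:
        return "<80%"
    if pct < 90.0:
        return "80% to <90%"
    if pct < 100.0:
        return "90% to <100%"
    return "100%"


def generate_cohort(
    config: CohortConfig | None = None, seed: int | None = None
) -> tuple[CohortData, GenerationTrace]:
    """Generate a seeded synthetic cohort.

    Identical (config, seed) pairs yield identical output.  ``seed``
    overrides ``config.seed`` when given.
    """
    cfg = config if config is not None else default_config()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    m = cfg.demographic_marginals
    a = cfg.adherence_model
    o = cfg.outcome_model
    interval = cfg.schedule_interval_days
    followup_cap = cfg.followup_months * 30

    cohort = CohortData()
    trace_rows = []
    width = max(4, len(str(cfg.n_patients)))
    study_start = date(2007, 1, 1)
    n_facilities = 16
    n_two_level = round(m["two_level_scale"] * n_facilities)

    for i in range(cfg.n_patients):
        pid = f"P{i + 1:0{width}d}"
        facility = int(rng.integers(1, n_facilities + 1))
        scale = "two_level" if facility <= n_two_level else "three_level"

        gender = _sample_cat(rng, m["gender"])
        if rng.random() < m["under_18"]:
            age = int(rng.integers(12, 18))
        else:
            lo, hi = _AGE_RANGES[_sample_cat(rng, m["age_band"])]
            age = int(rng.integers(lo, hi + 1))
        pmtct = gender == "female" and rng.random() < m["pmtct_female"]
        mu, sd = cfg.baseline_weight[gender]
        baseline_weight = max(30.0, float(rng.normal(mu, sd)))
        lo, hi = _CD4_RANGES[_sample_cat(rng, cfg.baseline_cd4_band_probs)]
        baseline_cd4 = int(rng.integers(lo, hi + 1))

        initiation = study_start + timedelta(days=int(rng.integers(0, 480)))
        collection = initiation + timedelta(days=int(rng.integers(244, 731)))
        follow_days = min(followup_cap, (collection - initiation).days)

        rec = PatientRecord(
            patient_id=pid,
            gender=gender,
            age_years=age,
            married=bool(rng.random() < m["married"]),
            education=_sample_cat(rng, m["education"]),
            occupation=_sample_cat(rng, m["occupation"]),
            living=_sample_cat(rng, m["living"]),
            support_partner=bool(rng.random() < m["support_partner"]),
            facility_id=f"F{facility:02d}",
            facility_management=_sample_cat(rng, m["facility_management"]),
            location=_sample_cat(rng, m["location"]),
            who_stage=int(_sample_cat(rng, m["who_stage"])),
            tb_at_initiation=bool(rng.random() < m["tb_at_initiation"]),
            pmtct_history=pmtct,
            prior_art_exposure=bool(rng.random() < m["prior_art_exposure"]),
            initiation_date=initiation,
            baseline_weight_kg=round(baseline_weight, 1),
            baseline_cd4=baseline_cd4,
            baseline_cd4_date=initiation - timedelta(days=int(rng.integers(7, 86))),
            data_collection_date=collection,
            selfreport_scale=scale,
        )
        cohort.add_patient(rec)

        # ---- behavior -----------------------------------------------------
        z = float(rng.normal(0.0, a.propensity_sd))
        p_ontime = _shifted_prob(a.prob_perfect_refill, z)
        p_miss = _shifted_prob(a.missed_visit_prob, -z)
        p_int = _shifted_prob(a.prob_long_interruption, -z)

        ild = a.interruption_length_distribution
        has_interruption = rng.random() < p_int
        if has_interruption:
            length = int(ild["min"]) + int(rng.geometric(1.0 / max(float(ild["mean_excess"]), 1.0))) - 1
            length = min(length, int(ild["max"]))
            s_lo, s_hi = ild.get("start_range", (30, 150))
            trigger_day = int(rng.integers(int(s_lo), int(s_hi) + 1))
        else:
            length = 0
            trigger_day = -1

        regimen = _FIRSTLINE[int(rng.integers(0, len(_FIRSTLINE)))]
        will_switch = rng.random() < 0.6
        switch_day = int(rng.integers(60, max(61, follow_days))) if will_switch else -1
        switch_to_pi = will_switch and rng.random() < 0.08
        switched = False

        b_i = float(rng.normal(0.0, o.residual_sds["weight_between"]))

        # ---- visit / dispensing walk --------------------------------------
        # pool tracking is O(1) per visit: pool is the days of supply
        # remaining immediately after the dispensing at the last visit.
        disp_days: list[tuple[int, int]] = [(0, interval)]
        visits: list[dict] = [{"day": 0, "sched": None, "code": None,
                               "regimen": regimen, "side": False}]
        last_day = 0
        pool_after = interval
        interruption_done = not has_interruption

        next_sched = interval
        while next_sched <= follow_days:
            if not interruption_done and next_sched >= trigger_day:
                # patient stops attending; returns `length` days after the
                # current supply runs out, giving an uncovered run of
                # exactly `length` days
                exhaust = last_day + pool_after
                actual = exhaust + length
                interruption_done = True
                if actual > follow_days:
                    break
            elif rng.random() < p_miss:
                next_sched += interval
                continue
            elif rng.random() < p_ontime:
                actual = next_sched
            else:
                band = _sample_cat(rng, a.refill_delay_distribution)
                d_lo, d_hi = _DELAY_RANGES[band]
                actual = next_sched + int(rng.integers(d_lo, d_hi + 1))
            if actual > follow_days:
                break

            if will_switch and not switched and actual >= switch_day:
                regimen = _PI_REGIMEN if switch_to_pi else \
                    _FIRSTLINE[(_FIRSTLINE.index(regimen) + 1) % len(_FIRSTLINE)]
                switched = True

            elapsed = actual - last_day
            lapse = (pool_after < elapsed) or (actual - next_sched > 3)
            pool_entering = max(0, pool_after - elapsed)

            if rng.random() < a.selfreport_record_prob:
                if not lapse:
                    code = 1 if rng.random() < 0.96 else 2
                elif rng.random() < a.selfreport_optimism:
                    code = 1
                else:
                    code = 2 if rng.random() < 0.85 else 3
            else:
                code = None

            visits.append({"day": actual, "sched": next_sched, "code": code,
                           "regimen": regimen, "side": bool(rng.random() < 0.08)})
            disp_days.append((actual, interval))
            pool_after = pool_entering + interval
            last_day = actual
            next_sched = actual + interval

        # ---- true coverage on the day grid --------------------------------
        horizon = max(follow_days, last_day + 1, 271)
        covered = _daily_coverage(disp_days, horizon)
        cum = np.cumsum(covered)           # cum[d-1] = covered days in [0, d)
        gap_prefix = _prefix_longest_gap(covered)

        def pct_at(day: int) -> float:
            return 100.0 * float(cum[day - 1]) / day

        def gap_at(day: int) -> bool:
            return bool(gap_prefix[day - 1] > 30)

        # ---- outcomes -----------------------------------------------------
        for v in visits:
            day = v["day"]
            if day == 0:
                v["weight"] = rec.baseline_weight_kg
                continue
            band = _coverage_band(pct_at(day))
            gain = _weight_curve_at(o.monthly_weight_gain_curve, day)
            if band == "<80%":
                gain += o.weight_penalty_low_coverage_kg
            elif band in o.weight_penalty_mid_bands:
                gain += o.weight_penalty_mid_bands[band]
            if gap_at(day):
                gain += o.weight_penalty_gap_kg
            noise = float(rng.normal(0.0, o.residual_sds["weight_within"]))
            v["weight"] = max(25.0, rec.baseline_weight_kg + gain + b_i + noise)

        for v in visits:
            cohort.add_visit(VisitEvent(
                patient_id=pid,
                actual_date=initiation + timedelta(days=v["day"]),
                scheduled_date=None if v["sched"] is None
                else initiation + timedelta(days=v["sched"]),
                weight_kg=round(v["weight"], 1),
                selfreport_code=v["code"],
                regimen_id=v["regimen"],
                side_effect_or_oi_flag=v["side"],
            ))
        regimen_by_day = {v["day"]: v["regimen"] for v in visits}
        for day, supply in disp_days:
            reg = regimen_by_day[day]
            cohort.add_dispensing(DispensingEvent(
                patient_id=pid,
                dispense_date=initiation + timedelta(days=day),
                components=tuple((drug, supply) for drug in _REGIMENS[reg]),
                regimen_id=reg,
                contains_pi=reg == _PI_REGIMEN,
            ))

        cohort.add_cd4(CD4Test(pid, rec.baseline_cd4_date, baseline_cd4))
        w_lo, w_hi = o.cd4_test_window_days
        hi_eff = min(w_hi, follow_days)
        if hi_eff > w_lo:
            test_day = int(rng.integers(w_lo, hi_eff + 1))
            band_t = _coverage_band(pct_at(test_day))
            gain = o.cd4_gain_full_coverage
            if band_t == "<80%":
                gain += o.cd4_penalty_low_coverage
            elif band_t in o.cd4_penalty_mid_bands:
                gain += o.cd4_penalty_mid_bands[band_t]
            gain += float(rng.normal(0.0, o.residual_sds["cd4"]))
            cohort.add_cd4(CD4Test(
                pid, initiation + timedelta(days=test_day),
                max(0, int(round(baseline_cd4 + gain))),
            ))

        # ---- trace --------------------------------------------------------
        t180 = min(180, horizon)
        trace_rows.append({
            "patient_id": pid,
            "propensity": z,
            "true_coverage_frac": float(cum[t180 - 1]) / t180,
            "true_gap_gt30": gap_at(t180),
            "true_gap_any": bool(gap_prefix[min(follow_days, horizon) - 1] > 30),
            "interruption_assigned": bool(has_interruption),
            "n_visits": len(visits),
        })

    cohort.sort_events()
    trace = GenerationTrace(pd.DataFrame(trace_rows).set_index("patient_id", drop=False))
    return cohort, trace
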
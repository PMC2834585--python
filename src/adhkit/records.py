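"""Cohort data model, delimited-file I/O, and the eligibility screen.

The unit of analysis is a patient initiating antiretroviral therapy (ART)
whose routine clinic records yield four event streams: an intake record,
a visit log, a pharmacy dispensing log, and CD4 test results.  Everything
downstream (indicator engine, correlation and outcome models) consumes the
:class:`CohortData` container built here.

File dialect: one CSV per event type (``patients.csv``, ``visits.csv``,
``dispensings.csv``, ``cd4.csv``), comma-delimited, UTF-8, ISO-8601 dates,
mandatory header row.  Malformed rows are collected into a rejects table,
never silently dropped.  See ``docs/data_dictionary.md`` for columns.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "PatientRecord",
    "VisitEvent",
    "DispensingEvent",
    "CD4Test",
    "CohortData",
    "EligibilityReport",
    "read_cohort",
    "write_cohort",
    "screen_eligibility",
    "age_band_of",
]

GENDERS = ("female", "male")
EDUCATION_LEVELS = ("none", "primary", "secondary+")
OCCUPATIONS = ("employed", "self-employed", "unemployed")
LIVING_SITUATIONS = ("alone", "with_child_only", "with_adult")
FACILITY_MANAGEMENT = ("government", "other")
LOCATIONS = ("capital", "other_urban", "rural")
SELFREPORT_SCALES = ("three_level", "two_level")
AGE_BANDS = ("<=30", "31-40", ">40")

#: Criteria applied in this fixed order; exclusion is attributed to the
#: first failure.
ELIGIBILITY_CRITERIA = (
    "age",
    "prior_art",
    "visit_continuity",
    "selfreport_availability",
    "dispensing_data",
    "cd4_availability",
)

#: Days of history used for the baseline CD4 window ("within 3 months prior").
BASELINE_CD4_WINDOW_DAYS = 91

#: Quarter length in days used to operationalize "two consecutive 3-month
#: periods" (initiation day = day 0; quarter 1 = days 1-91, quarter 2 = 92-182).
QUARTER_DAYS = 91


def age_band_of(age_years: int) -> str:
    """Map an age in years to the study's three analysis bands."""
    if age_years <= 30:
        return "<=30"
    if age_years <= 40:
        return "31-40"
    return ">40"


@dataclass(frozen=True)
class PatientRecord:
    """Static intake data for one subject.

    ``selfreport_scale`` carries the facility's self-report coding:
    ``three_level`` (perfect=1 / good=2 / poor=3) or ``two_level``
    (good-or-fair vs poor).  Two-level patients are excluded from
    self-report analyses downstream.
    """

    patient_id: str
    gender: str
    age_years: int
    married: bool
    education: str
    occupation: str
    living: str
    support_partner: bool
    facility_id: str
    facility_management: str
    location: str
    who_stage: int
    tb_at_initiation: bool
    pmtct_history: bool
    prior_art_exposure: bool
    initiation_date: date
    baseline_weight_kg: float
    baseline_cd4: int
    baseline_cd4_date: date
    data_collection_date: date
    selfreport_scale: str

    @property
    def age_band(self) -> str:
        return age_band_of(self.age_years)

    def validate(self) -> None:
        if self.gender not in GENDERS:
            raise ValueError(f"unknown gender {self.gender!r}")
        if self.age_years < 0:
            raise ValueError("age_years must be >= 0")
        if self.education not in EDUCATION_LEVELS:
            raise ValueError(f"unknown education {self.education!r}")
        if self.occupation not in OCCUPATIONS:
            raise ValueError(f"unknown occupation {self.occupation!r}")
        if self.living not in LIVING_SITUATIONS:
            raise ValueError(f"unknown living situation {self.living!r}")
        if self.facility_management not in FACILITY_MANAGEMENT:
            raise ValueError(f"unknown management {self.facility_management!r}")
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if self.who_stage not in (1, 2, 3, 4):
            raise ValueError(f"WHO stage must be 1-4, got {self.who_stage}")
        if self.selfreport_scale not in SELFREPORT_SCALES:
            raise ValueError(f"unknown scale {self.selfreport_scale!r}")
        if self.gender == "male" and self.pmtct_history:
            raise ValueError("pmtct_history must be false for males")
        if self.baseline_weight_kg <= 0:
            raise ValueError("baseline_weight_kg must be positive")
        if self.baseline_cd4 < 0:
            raise ValueError("baseline_cd4 must be non-negative")


@dataclass(frozen=True)
class VisitEvent:
    """One clinic attendance: actual vs scheduled date, weight, self-report."""

    patient_id: str
    actual_date: date
    scheduled_date: date | None = None
    weight_kg: float | None = None
    selfreport_code: int | None = None
    regimen_id: str | None = None
    side_effect_or_oi_flag: bool = False

    def validate(self) -> None:
        if self.weight_kg is not None and self.weight_kg <= 0:
            raise ValueError("weight_kg must be positive when present")
        if self.selfreport_code is not None and self.selfreport_code not in (1, 2, 3):
            raise ValueError(
                f"selfreport_code must be in {{1,2,3}}, got {self.selfreport_code}"
            )


@dataclass(frozen=True)
class DispensingEvent:
    """One pharmacy dispensing: per-component days of supply.

    ``components`` is a tuple of ``(drug_code, days_of_supply)`` pairs.  The
    effective supply of a multi-component regimen is the minimum across
    components: therapy is covered only while every drug is available.
    """

    patient_id: str
    dispense_date: date
    components: tuple[tuple[str, int], ...]
    regimen_id: str | None = None
    contains_pi: bool = False

    def validate(self) -> None:
        if not self.components:
            raise ValueError("dispensing must have at least one component")
        for drug, days in self.components:
            if days < 1:
                raise ValueError(f"days_of_supply must be >= 1 ({drug}: {days})")

    @property
    def effective_days_supply(self) -> int:
        return min(days for _, days in self.components)


@dataclass(frozen=True)
class CD4Test:
    patient_id: str
    test_date: date
    count: int

    def validate(self) -> None:
        if self.count < 0:
            raise ValueError("CD4 count must be non-negative")


@dataclass
class CohortData:
    """All records for a cohort, events keyed and date-sorted per patient."""

    patients: dict[str, PatientRecord] = field(default_factory=dict)
    visits: dict[str, list[VisitEvent]] = field(default_factory=dict)
    dispensings: dict[str, list[DispensingEvent]] = field(default_factory=dict)
    cd4_tests: dict[str, list[CD4Test]] = field(default_factory=dict)
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["file", "row", "reason"])
    )

    def __post_init__(self) -> None:
        for pid in self.patients:
            self.visits.setdefault(pid, [])
            self.dispensings.setdefault(pid, [])
            self.cd4_tests.setdefault(pid, [])

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def patient_ids(self) -> list[str]:
        return sorted(self.patients)

    def add_patient(self, rec: PatientRecord) -> None:
        rec.validate()
        self.patients[rec.patient_id] = rec
        self.visits.setdefault(rec.patient_id, [])
        self.dispensings.setdefault(rec.patient_id, [])
        self.cd4_tests.setdefault(rec.patient_id, [])

    def add_visit(self, ev: VisitEvent) -> None:
        ev.validate()
        self._check_pid(ev.patient_id)
        self.visits[ev.patient_id].append(ev)

    def add_dispensing(self, ev: DispensingEvent) -> None:
        ev.validate()
        self._check_pid(ev.patient_id)
        self.dispensings[ev.patient_id].append(ev)

    def add_cd4(self, ev: CD4Test) -> None:
        ev.validate()
        self._check_pid(ev.patient_id)
        self.cd4_tests[ev.patient_id].append(ev)

    def _check_pid(self, pid: str) -> None:
        if pid not in self.patients:
            raise KeyError(f"event references unknown patient {pid!r}")

    def sort_events(self) -> None:
        for pid in self.patients:
            self.visits[pid].sort(key=lambda v: (v.actual_date, v.patient_id))
            self.dispensings[pid].sort(key=lambda d: (d.dispense_date, d.patient_id))
            self.cd4_tests[pid].sort(key=lambda t: (t.test_date, t.patient_id))

    def validate(self) -> None:
        for rec in self.patients.values():
            rec.validate()
        for pid, evs in self.visits.items():
            self._check_pid(pid)
            for ev in evs:
                ev.validate()
                if ev.actual_date < self.patients[pid].initiation_date:
                    raise ValueError(
                        f"visit for {pid} on {ev.actual_date} precedes initiation"
                    )
        for pid, evs in self.dispensings.items():
            self._check_pid(pid)
            for ev in evs:
                ev.validate()
        for pid, evs in self.cd4_tests.items():
            self._check_pid(pid)
            for ev in evs:
                ev.validate()


@dataclass
class EligibilityReport:
    """Outcome of the inclusion screen.

    ``excluded`` maps each excluded patient to the first criterion it
    failed, in the fixed screening order.  ``exclusion_fractions`` are
    computed over all screened patients (first-failure attribution, so the
    per-criterion fractions sum to the overall exclusion fraction).
    """

    included_ids: list[str]
    excluded: dict[str, str]
    exclusion_fractions: dict[str, float]

    @property
    def n_screened(self) -> int:
        return len(self.included_ids) + len(self.excluded)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

PATIENT_COLUMNS = [
    "patient_id", "gender", "age_years", "married", "education", "occupation",
    "living", "support_partner", "facility_id", "facility_management",
    "location", "who_stage", "tb_at_initiation", "pmtct_history",
    "prior_art_exposure", "initiation_date", "baseline_weight_kg",
    "baseline_cd4", "baseline_cd4_date", "data_collection_date",
    "selfreport_scale",
]
VISIT_COLUMNS = [
    "patient_id", "actual_date", "scheduled_date", "weight_kg",
    "selfreport_code", "regimen_id", "side_effect_or_oi_flag",
]
DISPENSING_COLUMNS = [
    "patient_id", "dispense_date", "components", "regimen_id", "contains_pi",
]
CD4_COLUMNS = ["patient_id", "test_date", "count"]

FILE_NAMES = {
    "patients": "patients.csv",
    "visits": "visits.csv",
    "dispensings": "dispensings.csv",
    "cd4": "cd4.csv",
}

_MANDATORY = {
    "patients": PATIENT_COLUMNS,
    "visits": VISIT_COLUMNS,
    "dispensings": DISPENSING_COLUMNS,
    "cd4": CD4_COLUMNS,
}


def _parse_date(text: str) -> date:
    try:
        return date.fromisoformat(text.strip())
    except ValueError as exc:
        raise ValueError("bad date") from exc


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise ValueError(f"bad boolean {text!r}")


def _fmt_bool(b: bool) -> str:
    return "true" if b else "false"


def _parse_components(text: str) -> tuple[tuple[str, int], ...]:
    # "AZT:30;3TC:30;NVP:30"
    parts = []
    for chunk in text.strip().split(";"):
        drug, _, days = chunk.partition(":")
        if not drug or not days:
            raise ValueError(f"bad components field {text!r}")
        parts.append((drug, int(days)))
    return tuple(parts)


def _fmt_components(components: Iterable[tuple[str, int]]) -> str:
    return ";".join(f"{drug}:{days}" for drug, days in components)


def _blank(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == ""


def read_cohort(source: str | Path | Mapping[str, str | Path]) -> CohortData:
    """Read a cohort from a directory (or explicit path mapping) of CSVs.

    Malformed rows (unparseable dates, bad codes, events referencing unknown
    patients) are collected into ``CohortData.rejects`` with a reason; a
    missing mandatory column is a hard error naming the column.
    """
    if isinstance(source, (str, Path)):
        base = Path(source)
        paths = {k: base / v for k, v in FILE_NAMES.items()}
    else:
        paths = {k: Path(v) for k, v in source.items()}

    frames = {}
    for kind, path in paths.items():
        if not path.exists():
            raise FileNotFoundError(f"missing input file {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        for col in _MANDATORY[kind]:
            if col not in df.columns:
                raise ValueError(f"{path.name}: missing mandatory column {col!r}")
        frames[kind] = df

    cohort = CohortData()
    rejects: list[dict] = []

    def reject(kind: str, idx: int, reason: str) -> None:
        rejects.append({"file": FILE_NAMES[kind], "row": int(idx) + 2, "reason": reason})

    for idx, row in frames["patients"].iterrows():
        try:
            rec = PatientRecord(
                patient_id=row["patient_id"].strip(),
                gender=row["gender"].strip(),
                age_years=int(row["age_years"]),
                married=_parse_bool(row["married"]),
                education=row["education"].strip(),
                occupation=row["occupation"].strip(),
                living=row["living"].strip(),
                support_partner=_parse_bool(row["support_partner"]),
                facility_id=row["facility_id"].strip(),
                facility_management=row["facility_management"].strip(),
                location=row["location"].strip(),
                who_stage=int(row["who_stage"]),
                tb_at_initiation=_parse_bool(row["tb_at_initiation"]),
                pmtct_history=_parse_bool(row["pmtct_history"]),
                prior_art_exposure=_parse_bool(row["prior_art_exposure"]),
                initiation_date=_parse_date(row["initiation_date"]),
                baseline_weight_kg=float(row["baseline_weight_kg"]),
                baseline_cd4=int(row["baseline_cd4"]),
                baseline_cd4_date=_parse_date(row["baseline_cd4_date"]),
                data_collection_date=_parse_date(row["data_collection_date"]),
                selfreport_scale=row["selfreport_scale"].strip(),
            )
            rec.validate()
        except (ValueError, KeyError) as exc:
            reject("patients", idx, _reason(exc))
            continue
        cohort.add_patient(rec)

    for idx, row in frames["visits"].iterrows():
        try:
            ev = VisitEvent(
                patient_id=row["patient_id"].strip(),
                actual_date=_parse_date(row["actual_date"]),
                scheduled_date=None if _blank(row["scheduled_date"]) else _parse_date(row["scheduled_date"]),
                weight_kg=None if _blank(row["weight_kg"]) else float(row["weight_kg"]),
                selfreport_code=None if _blank(row["selfreport_code"]) else int(row["selfreport_code"]),
                regimen_id=None if _blank(row["regimen_id"]) else row["regimen_id"].strip(),
                side_effect_or_oi_flag=_parse_bool(row["side_effect_or_oi_flag"]),
            )
            cohort.add_visit(ev)
        except (ValueError, KeyError) as exc:
            reject("visits", idx, _reason(exc))

    for idx, row in frames["dispensings"].iterrows():
        try:
            ev = DispensingEvent(
                patient_id=row["patient_id"].strip(),
                dispense_date=_parse_date(row["dispense_date"]),
                components=_parse_components(row["components"]),
                regimen_id=None if _blank(row["regimen_id"]) else row["regimen_id"].strip(),
                contains_pi=_parse_bool(row["contains_pi"]),
            )
            cohort.add_dispensing(ev)
        except (ValueError, KeyError) as exc:
            reject("dispensings", idx, _reason(exc))

    for idx, row in frames["cd4"].iterrows():
        try:
            ev = CD4Test(
                patient_id=row["patient_id"].strip(),
                test_date=_parse_date(row["test_date"]),
                count=int(row["count"]),
            )
            cohort.add_cd4(ev)
        except (ValueError, KeyError) as exc:
            reject("cd4", idx, _reason(exc))

    cohort.sort_events()
    cohort.rejects = pd.DataFrame(rejects, columns=["file", "row", "reason"])
    return cohort


def _reason(exc: Exception) -> str:
    msg = str(exc)
    if "fromisoformat" in msg or "Invalid isoformat" in msg:
        return "bad date"
    if isinstance(exc, KeyError):
        return f"unknown patient {msg}"
    return msg or exc.__class__.__name__


def write_cohort(cohort: CohortData, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as CSVs readable by :func:`read_cohort`.

    Row order is deterministic: (patient_id, date).  Absent optional fields
    are written as empty strings, not sentinels.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.sort_events()

    prows = []
    for pid in cohort.patient_ids():
        r = cohort.patients[pid]
        prows.append({
            "patient_id": r.patient_id,
            "gender": r.gender,
            "age_years": r.age_years,
            "married": _fmt_bool(r.married),
            "education": r.education,
            "occupation": r.occupation,
            "living": r.living,
            "support_partner": _fmt_bool(r.support_partner),
            "facility_id": r.facility_id,
            "facility_management": r.facility_management,
            "location": r.location,
            "who_stage": r.who_stage,
            "tb_at_initiation": _fmt_bool(r.tb_at_initiation),
            "pmtct_history": _fmt_bool(r.pmtct_history),
            "prior_art_exposure": _fmt_bool(r.prior_art_exposure),
            "initiation_date": r.initiation_date.isoformat(),
            "baseline_weight_kg": f"{r.baseline_weight_kg:.1f}",
            "baseline_cd4": r.baseline_cd4,
            "baseline_cd4_date": r.baseline_cd4_date.isoformat(),
            "data_collection_date": r.data_collection_date.isoformat(),
            "selfreport_scale": r.selfreport_scale,
        })
    vrows = []
    for pid in cohort.patient_ids():
        for v in cohort.visits[pid]:
            vrows.append({
                "patient_id": v.patient_id,
                "actual_date": v.actual_date.isoformat(),
                "scheduled_date": "" if v.scheduled_date is None else v.scheduled_date.isoformat(),
                "weight_kg": "" if v.weight_kg is None else f"{v.weight_kg:.1f}",
                "selfreport_code": "" if v.selfreport_code is None else v.selfreport_code,
                "regimen_id": v.regimen_id or "",
                "side_effect_or_oi_flag": _fmt_bool(v.side_effect_or_oi_flag),
            })
    drows = []
    for pid in cohort.patient_ids():
        for d in cohort.dispensings[pid]:
            drows.append({
                "patient_id": d.patient_id,
                "dispense_date": d.dispense_date.isoformat(),
                "components": _fmt_components(d.components),
                "regimen_id": d.regimen_id or "",
                "contains_pi": _fmt_bool(d.contains_pi),
            })
    crows = []
    for pid in cohort.patient_ids():
        for t in cohort.cd4_tests[pid]:
            crows.append({
                "patient_id": t.patient_id,
                "test_date": t.test_date.isoformat(),
                "count": t.count,
            })

    paths = {}
    for kind, rows, cols in (
        ("patients", prows, PATIENT_COLUMNS),
        ("visits", vrows, VISIT_COLUMNS),
        ("dispensings", drows, DISPENSING_COLUMNS),
        ("cd4", crows, CD4_COLUMNS),
    ):
        path = out / FILE_NAMES[kind]
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        paths[kind] = path
    if len(cohort.rejects):
        rpath = out / "rejects.csv"
        cohort.rejects.to_csv(rpath, index=False)
        paths["rejects"] = rpath
    return paths


# ---------------------------------------------------------------------------
# Eligibility screen
# ---------------------------------------------------------------------------

def screen_eligibility(cohort: CohortData, asof_months: int = 6) -> EligibilityReport:
    """Classify every patient against the inclusion criteria, in order.

    Criteria, applied in the fixed order below with exclusion attributed to
    the first failure:

    1. ``age`` — at least 18 years old at initiation.
    2. ``prior_art`` — no previous ART exposure (short-course prophylaxis to
       prevent mother-to-child transmission does not count).
    3. ``visit_continuity`` — at least one clinic visit in each of the first
       two consecutive 3-month periods after initiation (days 1-91 and
       92-182; generalized to ``asof_months // 3`` quarters).
    4. ``selfreport_availability`` — at least one adherence self-report
       recorded in those quarters.
    5. ``dispensing_data`` — at least one dispensing record during follow-up.
    6. ``cd4_availability`` — a baseline CD4 test within 3 months (91 days)
       before initiation.

    Screening never fails: unclassifiable data counts as failing the
    relevant criterion.
    """
    n_quarters = max(1, asof_months // 3)
    included: list[str] = []
    excluded: dict[str, str] = {}

    for pid in cohort.patient_ids():
        rec = cohort.patients[pid]
        reason = _first_failure(rec, cohort, n_quarters)
        if reason is None:
            included.append(pid)
        else:
            excluded[pid] = reason

    n = max(1, cohort.n_patients)
    fractions = {
        c: sum(1 for r in excluded.values() if r == c) / n
        for c in ELIGIBILITY_CRITERIA
    }
    return EligibilityReport(
        included_ids=included, excluded=excluded, exclusion_fractions=fractions
    )


def _first_failure(rec: PatientRecord, cohort: CohortData, n_quarters: int) -> str | None:
    if rec.age_years < 18:
        return "age"
    if rec.prior_art_exposure:
        return "prior_art"

    init = rec.initiation_date
    visits = cohort.visits.get(rec.patient_id, [])
    visit_days = [(v.actual_date - init).days for v in visits]
    for q in range(n_quarters):
        lo, hi = q * QUARTER_DAYS + 1, (q + 1) * QUARTER_DAYS
        if not any(lo <= d <= hi for d in visit_days):
            return "visit_continuity"

    window_end = n_quarters * QUARTER_DAYS
    has_selfreport = any(
        v.selfreport_code is not None
        and 1 <= (v.actual_date - init).days <= window_end
        for v in visits
    ) or any(
        v.selfreport_code is not None and (v.actual_date - init).days == 0
        for v in visits
    )
    if not has_selfreport:
        return "selfreport_availability"

    if not cohort.dispensings.get(rec.patient_id):
        return "dispensing_data"

    lag = (init - rec.baseline_cd4_date).days
    if not (0 <= lag <= BASELINE_CD4_WINDOW_DAYS):
        return "cd4_availability"
    return None
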
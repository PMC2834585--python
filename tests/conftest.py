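"""Shared fixtures: a small hand-built cohort and generated cohorts."""

from datetime import date, timedelta

import pytest

from adhkit.records import (
    CD4Test,
    CohortData,
    DispensingEvent,
    PatientRecord,
    VisitEvent,
)

D0 = date(2007, 3, 1)


def make_patient(pid="P1", **overrides) -> PatientRecord:
    fields = dict(
        patient_id=pid,
        gender="female",
        age_years=34,
        married=True,
        education="primary",
        occupation="employed",
        living="with_adult",
        support_partner=True,
        facility_id="F01",
        facility_management="government",
        location="capital",
        who_stage=3,
        tb_at_initiation=False,
        pmtct_history=False,
        prior_art_exposure=False,
        initiation_date=D0,
        baseline_weight_kg=52.9,
        baseline_cd4=150,
        baseline_cd4_date=D0 - timedelta(days=30),
        data_collection_date=D0 + timedelta(days=540),
        selfreport_scale="three_level",
    )
    fields.update(overrides)
    return PatientRecord(**fields)


def monthly_regimen_dispensing(pid, day, supply=30, regimen="AZT-3TC-NVP"):
    drugs = regimen.split("-")
    return DispensingEvent(
        patient_id=pid,
        dispense_date=D0 + timedelta(days=day),
        components=tuple((d, supply) for d in drugs),
        regimen_id=regimen,
    )


@pytest.fixture
def small_cohort() -> CohortData:
    """Three patients: adherent P1, gap-prone P2, under-age P3."""
    cohort = CohortData()

    p1 = make_patient("P1")
    cohort.add_patient(p1)
    for day in (0, 30, 60, 90, 120, 150, 180):
        sched = None if day == 0 else day
        cohort.add_visit(VisitEvent(
            "P1", D0 + timedelta(days=day),
            scheduled_date=None if sched is None else D0 + timedelta(days=sched),
            weight_kg=53.0 + day / 60.0,
            selfreport_code=None if day == 0 else 1,
            regimen_id="AZT-3TC-NVP",
        ))
        cohort.add_dispensing(monthly_regimen_dispensing("P1", day))
    cohort.add_cd4(CD4Test("P1", D0 - timedelta(days=30), 150))
    cohort.add_cd4(CD4Test("P1", D0 + timedelta(days=182), 300))

    p2 = make_patient("P2", gender="male", baseline_weight_kg=57.2,
                      pmtct_history=False)
    cohort.add_patient(p2)
    # misses a month: 45-day hole between supply exhaustion (day 30) and
    # the day-75 refill -> uncovered days 30..74
    for day in (0, 75, 105, 135, 165):
        cohort.add_visit(VisitEvent(
            "P2", D0 + timedelta(days=day),
            scheduled_date=None if day == 0 else D0 + timedelta(days=day - 15),
            weight_kg=57.0,
            selfreport_code=None if day == 0 else 2,
            regimen_id="AZT-3TC-NVP",
        ))
        cohort.add_dispensing(monthly_regimen_dispensing("P2", day))
    cohort.add_cd4(CD4Test("P2", D0 - timedelta(days=60), 90))
    cohort.add_cd4(CD4Test("P2", D0 + timedelta(days=200), 150))

    p3 = make_patient("P3", age_years=17)
    cohort.add_patient(p3)
    cohort.add_visit(VisitEvent("P3", D0 + timedelta(days=20),
                                selfreport_code=1, weight_kg=50.0))
    cohort.add_dispensing(monthly_regimen_dispensing("P3", 20))
    cohort.add_cd4(CD4Test("P3", D0 - timedelta(days=10), 200))

    cohort.sort_events()
    return cohort
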
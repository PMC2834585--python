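"""The eight adherence and attendance indicators, computed cumulatively.

All measures are evaluated "as of" a date (typically a clinic visit),
covering the half-open window from ART initiation (day 0) up to but not
including the as-of day.  Coverage uses a supply-pool model: each
dispensing adds its effective days of supply to a pool, one unit is
consumed per day while the pool is positive, and unfinished supply carries
over across early refills.  A day is covered iff the pool is positive on
entering that day (same-day dispensings count).

The exhaustion-timeliness measure deliberately does NOT carry supply over
from earlier visits: a visit is timely iff it occurs on or before the
expected finish date of the previous visit's dispensing alone.  This
asymmetry mirrors how the measure is defined for settings without
scheduled-visit data, and is a known source of pessimistic bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Sequence

import pandas as pd

from .records import CohortData, DispensingEvent, PatientRecord, VisitEvent

__all__ = [
    "CoverageTimeline",
    "IndicatorSnapshot",
    "build_coverage_timeline",
    "pct_days_covered",
    "longest_gap",
    "gap_exceeds",
    "avg_selfreport",
    "selfreport_flags",
    "visit_timeliness",
    "pct_visits_before_exhaustion",
    "snapshot_at",
    "select_index_visit",
    "categorize_coverage",
    "snapshot_table",
    "TABLE2_BANDS",
    "MODEL_BANDS",
    "FOLLOWUP_CAP_DAYS",
    "GAP_THRESHOLD_DAYS",
]

#: Follow-up horizon: 18 months of observation, in whole days.
FOLLOWUP_CAP_DAYS = 548

#: A treatment gap is flagged when strictly more than this many consecutive
#: days are uncovered.
GAP_THRESHOLD_DAYS = 30

TABLE2_BANDS = (
    "<80%", "80% to <85%", "85% to <90%", "90% to <95%", "95% to <100%", "100%",
)
MODEL_BANDS = ("<80%", "80% to <90%", "90% to <100%", "100%")


@dataclass
class CoverageTimeline:
    """Covered-day intervals for one patient's window [0, window_end_day).

    ``intervals`` are disjoint, sorted, half-open ``[start_day, end_day)``
    runs of covered days.  ``supply_pool_trace`` records ``(day, pool)``
    after each dispensing is added, for audit.
    """

    patient_id: str
    window_end_day: int
    intervals: list[tuple[int, int]] = field(default_factory=list)
    supply_pool_trace: list[tuple[int, int]] = field(default_factory=list)
    n_ignored_after_window: int = 0

    @property
    def covered_days(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def is_covered(self, day: int) -> bool:
        return any(s <= day < e for s, e in self.intervals)

    def gaps(self) -> list[tuple[int, int]]:
        """Uncovered runs within the window, as half-open intervals."""
        out = []
        prev = 0
        for s, e in self.intervals:
            if s > prev:
                out.append((prev, s))
            prev = e
        if prev < self.window_end_day:
            out.append((prev, self.window_end_day))
        return out


def build_coverage_timeline(
    dispensings: Iterable[DispensingEvent],
    initiation: date,
    asof: date,
) -> CoverageTimeline:
    """Build the covered-day timeline from dispensing events.

    Supply accumulates into a pool on each dispensing day (carryover of
    unfinished supply); one unit is consumed per covered day.  Dispensings
    on or after ``asof`` fall outside the half-open window and are ignored
    (counted in ``n_ignored_after_window``); a dispensing before initiation
    is a hard error.
    """
    window = (asof - initiation).days
    if window < 1:
        raise ValueError("asof must be after initiation")

    by_day: dict[int, int] = {}
    pid = ""
    ignored = 0
    for ev in dispensings:
        pid = ev.patient_id
        d = (ev.dispense_date - initiation).days
        if d < 0:
            raise ValueError(
                f"dispensing on {ev.dispense_date} precedes initiation {initiation}"
            )
        if d >= window:
            ignored += 1
            continue
        by_day[d] = by_day.get(d, 0) + ev.effective_days_supply

    tl = CoverageTimeline(patient_id=pid, window_end_day=window,
                          n_ignored_after_window=ignored)
    pool = 0
    prev = 0
    intervals: list[tuple[int, int]] = []
    for day in sorted(by_day):
        if pool > 0:
            run_end = min(prev + pool, day)
            intervals.append((prev, run_end))
            pool -= min(pool, day - prev)
        pool += by_day[day]
        prev = day
        tl.supply_pool_trace.append((day, pool))
    if pool > 0:
        intervals.append((prev, min(prev + pool, window)))

    # merge touching runs
    merged: list[tuple[int, int]] = []
    for s, e in intervals:
        if e <= s:
            continue
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    tl.intervals = merged
    return tl


def pct_days_covered(timeline: CoverageTimeline) -> float:
    """Percent of window days covered, in [0, 100]."""
    if timeline.window_end_day < 1:
        raise ValueError("empty coverage window")
    return 100.0 * timeline.covered_days / timeline.window_end_day


def longest_gap(timeline: CoverageTimeline) -> int:
    """Length in days of the longest uncovered run within the window."""
    gaps = timeline.gaps()
    return max((e - s for s, e in gaps), default=0)


def gap_exceeds(timeline: CoverageTimeline, threshold: int = GAP_THRESHOLD_DAYS) -> bool:
    """True iff some uncovered run is strictly longer than ``threshold``."""
    return longest_gap(timeline) > threshold


def _codes_upto(visits: Iterable[VisitEvent], asof: date) -> list[int]:
    codes = []
    for v in visits:
        if v.actual_date <= asof and v.selfreport_code is not None:
            if v.selfreport_code not in (1, 2, 3):
                raise ValueError(f"self-report code {v.selfreport_code} outside 1-3")
            codes.append(v.selfreport_code)
    return codes


def avg_selfreport(visits: Iterable[VisitEvent], asof: date) -> float | None:
    """Mean of recorded self-report codes at visits up to ``asof``.

    Returns None when no codes were recorded.
    """
    codes = _codes_upto(visits, asof)
    if not codes:
        return None
    return sum(codes) / len(codes)


def selfreport_flags(visits: Iterable[VisitEvent], asof: date) -> tuple[bool, bool]:
    """(ever reported poor, ever reported less than perfect) up to ``asof``."""
    codes = _codes_upto(visits, asof)
    return any(c == 3 for c in codes), any(c > 1 for c in codes)


def visit_timeliness(
    visits: Iterable[VisitEvent], asof: date
) -> tuple[float | None, float | None]:
    """Percent of visits on/before schedule and within 3 days after.

    Both percentages share one denominator: visits up to ``asof`` that have
    a recorded scheduled date.  Returns (None, None) when that denominator
    is zero.
    """
    n = on_time = within3 = 0
    for v in visits:
        if v.actual_date > asof or v.scheduled_date is None:
            continue
        n += 1
        if v.actual_date <= v.scheduled_date:
            on_time += 1
        if v.actual_date <= v.scheduled_date + timedelta(days=3):
            within3 += 1
    if n == 0:
        return None, None
    return 100.0 * on_time / n, 100.0 * within3 / n


def pct_visits_before_exhaustion(
    visits: Sequence[VisitEvent],
    dispensings: Sequence[DispensingEvent],
    asof: date,
) -> float | None:
    """Percent of visits occurring before the previous dispensing ran out.

    For each visit after the first, the visit is timely iff its date is on
    or before (previous visit's dispensing date + that dispensing's days of
    supply).  Supply left over from still-earlier visits is deliberately
    not credited.  Visit pairs whose previous visit has no same-day
    dispensing are excluded from the denominator.  Returns None when the
    denominator is zero.
    """
    vs = [v for v in visits if v.actual_date <= asof]
    vs.sort(key=lambda v: v.actual_date)
    disp_by_date: dict[date, int] = {}
    for d in dispensings:
        if d.dispense_date <= asof:
            supply = d.effective_days_supply
            if d.dispense_date in disp_by_date:
                disp_by_date[d.dispense_date] = min(disp_by_date[d.dispense_date], supply)
            else:
                disp_by_date[d.dispense_date] = supply

    n = timely = 0
    for prev, cur in zip(vs, vs[1:]):
        supply = disp_by_date.get(prev.actual_date)
        if supply is None:
            continue
        n += 1
        if cur.actual_date <= prev.actual_date + timedelta(days=supply):
            timely += 1
    if n == 0:
        return None
    return 100.0 * timely / n


@dataclass
class IndicatorSnapshot:
    """All eight measures for one patient, cumulative to ``asof_day``."""

    patient_id: str
    asof_day: int
    avg_selfreport: float | None
    any_poor_selfreport: bool | None
    any_imperfect_selfreport: bool | None
    pct_days_covered: float
    gap_gt30: bool
    longest_gap_days: int
    pct_visits_on_or_before: float | None
    pct_visits_within_3d: float | None
    pct_visits_before_exhaustion: float | None
    n_visits: int
    n_selfreports: int


def snapshot_at(
    patient: PatientRecord,
    visits: Sequence[VisitEvent],
    dispensings: Sequence[DispensingEvent],
    asof: date,
) -> IndicatorSnapshot:
    """Evaluate every measure for one patient as of one date.

    Self-report fields are absent (None) for patients at facilities using
    the two-level coding, whose reports are not comparable with the 1/2/3
    scale.  Snapshots beyond the 18-month horizon or beyond the data
    collection date are refused, as is an as-of date before the first visit.
    """
    init = patient.initiation_date
    asof_day = (asof - init).days
    cap = min(FOLLOWUP_CAP_DAYS, (patient.data_collection_date - init).days)
    if asof_day > cap:
        raise ValueError(
            f"asof day {asof_day} beyond observation horizon ({cap} days)"
        )
    dated = [v for v in visits]
    if not dated or asof < min(v.actual_date for v in dated):
        raise ValueError("asof precedes the first recorded visit")

    tl = build_coverage_timeline(dispensings, init, asof)
    pct = pct_days_covered(tl)
    lg = longest_gap(tl)

    if patient.selfreport_scale == "three_level":
        avg = avg_selfreport(visits, asof)
        any_poor, any_imp = selfreport_flags(visits, asof)
        n_sr = len(_codes_upto(visits, asof))
        if avg is None:
            any_poor = any_imp = None
    else:
        avg, any_poor, any_imp, n_sr = None, None, None, 0

    on_time, within3 = visit_timeliness(visits, asof)
    exhaustion = pct_visits_before_exhaustion(visits, dispensings, asof)
    n_visits = sum(1 for v in visits if v.actual_date <= asof)

    return IndicatorSnapshot(
        patient_id=patient.patient_id,
        asof_day=asof_day,
        avg_selfreport=avg,
        any_poor_selfreport=any_poor,
        any_imperfect_selfreport=any_imp,
        pct_days_covered=pct,
        gap_gt30=lg > GAP_THRESHOLD_DAYS,
        longest_gap_days=lg,
        pct_visits_on_or_before=on_time,
        pct_visits_within_3d=within3,
        pct_visits_before_exhaustion=exhaustion,
        n_visits=n_visits,
        n_selfreports=n_sr,
    )


def select_index_visit(
    visits: Sequence[VisitEvent], initiation: date, target_day: int = 180
) -> date:
    """Date of the visit nearest to ``target_day`` after initiation.

    Equidistant ties break toward the earlier visit.
    """
    if not visits:
        raise ValueError("patient has no visits")
    best = min(
        visits,
        key=lambda v: (abs((v.actual_date - initiation).days - target_day),
                       v.actual_date),
    )
    return best.actual_date


def categorize_coverage(pct: float, scheme: str = "model") -> str:
    """Band a coverage percent.

    ``table2`` uses the six descriptive bands (<80, 80-<85, 85-<90, 90-<95,
    95-<100, 100); ``model`` uses the four regression bands with exact-100
    as reference.  Bands are upper-exclusive except the exact-100 band.
    """
    if not (0.0 <= pct <= 100.0):
        raise ValueError(f"coverage percent {pct} outside [0, 100]")
    if scheme == "table2":
        edges = [(80, "<80%"), (85, "80% to <85%"), (90, "85% to <90%"),
                 (95, "90% to <95%"), (100, "95% to <100%")]
    elif scheme == "model":
        edges = [(80, "<80%"), (90, "80% to <90%"), (100, "90% to <100%")]
    else:
        raise ValueError(f"unknown banding scheme {scheme!r}")
    for upper, label in edges:
        if pct < upper:
            return label
    return "100%"


def snapshot_table(
    cohort: CohortData,
    patient_ids: Sequence[str] | None = None,
    target_day: int = 180,
) -> pd.DataFrame:
    """Index-visit snapshots for a cohort, one row per patient.

    The as-of date for each patient is the visit nearest ``target_day``
    days after initiation (ties to the earlier visit).  Patients without
    visits are skipped.
    """
    ids = list(patient_ids) if patient_ids is not None else cohort.patient_ids()
    rows = []
    for pid in ids:
        visits = cohort.visits.get(pid, [])
        if not visits:
            continue
        rec = cohort.patients[pid]
        asof = select_index_visit(visits, rec.initiation_date, target_day)
        snap = snapshot_at(rec, visits, cohort.dispensings.get(pid, []), asof)
        row = snap.__dict__.copy()
        row["selfreport_scale"] = rec.selfreport_scale
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.set_index("patient_id", drop=False)
    return df
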
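"""Indicator engine: coverage pool, gaps, self-report, timeliness."""

from datetime import date, timedelta

import numpy as np
import pytest

from adhkit.indicators import (
    avg_selfreport,
    build_coverage_timeline,
    categorize_coverage,
    gap_exceeds,
    longest_gap,
    pct_days_covered,
    pct_visits_before_exhaustion,
    select_index_visit,
    selfreport_flags,
    snapshot_at,
    visit_timeliness,
)
from adhkit.records import DispensingEvent, VisitEvent
from conftest import D0, make_patient, monthly_regimen_dispensing
from _oracles import naive_daily_coverage, naive_longest_gap, naive_exhaustion_timeliness


def disp(day, supply=30, pid="P1"):
    return DispensingEvent(pid, D0 + timedelta(days=day), (("AZT", supply),))


def visit(day, sched=None, code=None, pid="P1", weight=None):
    return VisitEvent(pid, D0 + timedelta(days=day),
                      scheduled_date=None if sched is None else D0 + timedelta(days=sched),
                      selfreport_code=code, weight_kg=weight)


class TestCoverageTimeline:
    @pytest.mark.parametrize("days,asof,expected_covered", [
        ([0, 30, 60], 90, 90),        # seamless refills
        ([0, 45], 90, 60),            # 15-day hole, tail runs out at day 75
        ([0, 20], 60, 60),            # early refill stockpiles (pool hits 40)
    ])
    def test_covered_day_counts(self, days, asof, expected_covered):
        tl = build_coverage_timeline([disp(d) for d in days], D0,
                                     D0 + timedelta(days=asof))
        assert tl.covered_days == expected_covered
        # cross-check against the naive per-day pool walk
        oracle = naive_daily_coverage([(d, 30) for d in days], asof)
        assert tl.covered_days == sum(oracle)

    def test_gap_interval_structure(self):
        tl = build_coverage_timeline([disp(0), disp(45)], D0,
                                     D0 + timedelta(days=90))
        assert tl.intervals == [(0, 30), (45, 75)]
        assert tl.gaps() == [(30, 45), (75, 90)]

    def test_stockpile_pool_trace(self):
        tl = build_coverage_timeline([disp(0), disp(20)], D0,
                                     D0 + timedelta(days=60))
        assert (20, 40) in tl.supply_pool_trace

    def test_dispensing_before_initiation_is_error(self):
        with pytest.raises(ValueError, match="precedes initiation"):
            build_coverage_timeline([disp(0), DispensingEvent(
                "P1", D0 - timedelta(days=1), (("AZT", 30),))],
                D0, D0 + timedelta(days=30))

    def test_dispensing_at_or_after_asof_ignored(self):
        tl = build_coverage_timeline([disp(0), disp(90)], D0,
                                     D0 + timedelta(days=90))
        assert tl.covered_days == 30
        assert tl.n_ignored_after_window == 1

    def test_multi_component_supply_is_minimum(self):
        ev = DispensingEvent("P1", D0, (("AZT", 30), ("3TC", 14), ("NVP", 30)))
        tl = build_coverage_timeline([ev], D0, D0 + timedelta(days=30))
        assert tl.covered_days == 14

    def test_pct_days_covered_values(self):
        tl = build_coverage_timeline([disp(0), disp(45)], D0,
                                     D0 + timedelta(days=90))
        assert pct_days_covered(tl) == pytest.approx(100 * 60 / 90)
        full = build_coverage_timeline([disp(0)], D0, D0 + timedelta(days=30))
        assert pct_days_covered(full) == 100.0
        empty = build_coverage_timeline([], D0, D0 + timedelta(days=30))
        assert pct_days_covered(empty) == 0.0


class TestGapDetection:
    def test_31_day_gap_flagged(self):
        # supply days 0 and 61: uncovered days 30..60 inclusive = 31 days
        tl = build_coverage_timeline([disp(0), disp(61)], D0,
                                     D0 + timedelta(days=91))
        assert longest_gap(tl) == 31
        assert gap_exceeds(tl)

    def test_exactly_30_day_gap_not_flagged(self):
        # strict inequality: a 30-day hole does not trip the flag
        tl = build_coverage_timeline([disp(0), disp(60)], D0,
                                     D0 + timedelta(days=90))
        assert longest_gap(tl) == 30
        assert not gap_exceeds(tl)

    def test_full_coverage_has_no_gap(self):
        tl = build_coverage_timeline([disp(0), disp(30)], D0,
                                     D0 + timedelta(days=60))
        assert longest_gap(tl) == 0
        assert not gap_exceeds(tl)

    def test_trailing_nonrefill_counts_as_gap(self):
        # patient stops refilling: uncovered days accrue up to asof
        tl = build_coverage_timeline([disp(0)], D0, D0 + timedelta(days=90))
        assert longest_gap(tl) == 60
        assert gap_exceeds(tl)


class TestRandomHistoriesMatchOracle:
    def test_interval_engine_equals_day_by_day_simulation(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(0, 10))
            days = sorted(rng.choice(300, size=n, replace=False)) if n else []
            supplies = rng.integers(1, 60, size=n)
            window = int(rng.integers(30, 400))
            events = [disp(int(d), int(s)) for d, s in zip(days, supplies)]
            tl = build_coverage_timeline(events, D0, D0 + timedelta(days=window))
            oracle = naive_daily_coverage(
                [(int(d), int(s)) for d, s in zip(days, supplies)], window)
            assert tl.covered_days == sum(oracle)
            assert longest_gap(tl) == naive_longest_gap(oracle)
            for day in range(window):
                assert tl.is_covered(day) == oracle[day]

    def test_adding_a_dispensing_never_hurts(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(1, 8))
            days = sorted(int(d) for d in rng.choice(200, size=n, replace=False))
            events = [disp(d) for d in days]
            window = D0 + timedelta(days=240)
            base = build_coverage_timeline(events, D0, window)
            extra_day = int(rng.integers(0, 240))
            extended = build_coverage_timeline(
                events + [disp(extra_day, int(rng.integers(1, 45)))], D0, window)
            assert pct_days_covered(extended) >= pct_days_covered(base)
            assert longest_gap(extended) <= longest_gap(base)


class TestSelfReport:
    def test_average_of_codes(self):
        visits = [visit(30, code=1), visit(60, code=1), visit(90, code=2)]
        assert avg_selfreport(visits, D0 + timedelta(days=90)) == pytest.approx(4 / 3)

    def test_all_perfect_and_no_codes(self):
        visits = [visit(30, code=1), visit(60, code=1)]
        assert avg_selfreport(visits, D0 + timedelta(days=60)) == 1.0
        assert avg_selfreport([visit(30)], D0 + timedelta(days=60)) is None

    @pytest.mark.parametrize("codes,expected", [
        ([1, 2, 1], (False, True)),
        ([1, 1], (False, False)),
        ([3], (True, True)),
    ])
    def test_flags(self, codes, expected):
        visits = [visit(30 * (i + 1), code=c) for i, c in enumerate(codes)]
        assert selfreport_flags(visits, D0 + timedelta(days=360)) == expected

    def test_bad_code_is_error(self):
        bad = VisitEvent("P1", D0 + timedelta(days=30), selfreport_code=None)
        object.__setattr__(bad, "selfreport_code", 5)  # bypass constructor check
        with pytest.raises(ValueError, match="outside 1-3"):
            avg_selfreport([bad], D0 + timedelta(days=60))


class TestTimeliness:
    def test_boundaries(self):
        asof = D0 + timedelta(days=200)
        on_time, within3 = visit_timeliness([visit(30, sched=30)], asof)
        assert (on_time, within3) == (100.0, 100.0)
        on_time, within3 = visit_timeliness([visit(33, sched=30)], asof)
        assert (on_time, within3) == (0.0, 100.0)
        on_time, within3 = visit_timeliness([visit(34, sched=30)], asof)
        assert (on_time, within3) == (0.0, 0.0)

    def test_unscheduled_visits_excluded_from_denominator(self):
        asof = D0 + timedelta(days=200)
        visits = [visit(0), visit(30, sched=30), visit(65, sched=60)]
        on_time, within3 = visit_timeliness(visits, asof)
        assert on_time == 50.0 and within3 == 50.0
        assert visit_timeliness([visit(0)], asof) == (None, None)

    def test_within3_dominates_on_time(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            visits = [visit(int(30 * k + rng.integers(-2, 10)), sched=30 * k)
                      for k in range(1, 7)]
            on_time, within3 = visit_timeliness(visits, D0 + timedelta(days=400))
            assert within3 >= on_time


class TestExhaustionTimeliness:
    def test_boundary_and_no_carryover(self):
        asof = D0 + timedelta(days=200)
        visits = [visit(0), visit(30)]
        disps = [disp(0), disp(30)]
        assert pct_visits_before_exhaustion(visits, disps, asof) == 100.0
        # day 31 is late even though earlier stockpiled supply would cover it
        visits = [visit(0), visit(20), visit(51)]
        disps = [disp(0), disp(20), disp(51)]
        assert pct_visits_before_exhaustion(visits, disps, asof) == 50.0

    def test_matches_arithmetic_oracle_on_random_histories(self):
        rng = np.random.default_rng(11)
        asof = D0 + timedelta(days=400)
        for _ in range(100):
            days = sorted(int(d) for d in rng.choice(360, size=6, replace=False))
            supplies = [int(s) for s in rng.integers(14, 45, size=6)]
            visits = [visit(d) for d in days]
            disps = [disp(d, s) for d, s in zip(days, supplies)]
            got = pct_visits_before_exhaustion(visits, disps, asof)
            expected = naive_exhaustion_timeliness(days, list(zip(days, supplies)))
            assert got == pytest.approx(expected)

    def test_visit_without_dispensing_excluded(self):
        asof = D0 + timedelta(days=200)
        visits = [visit(0), visit(30), visit(60)]
        disps = [disp(0)]  # day-30 visit has no dispensing
        # pair (0 -> 30) timely; pair (30 -> 60) dropped
        assert pct_visits_before_exhaustion(visits, disps, asof) == 100.0


class TestSnapshotAndIndexVisit:
    def test_fully_adherent_snapshot(self, small_cohort):
        rec = small_cohort.patients["P1"]
        snap = snapshot_at(rec, small_cohort.visits["P1"],
                           small_cohort.dispensings["P1"],
                           D0 + timedelta(days=180))
        assert snap.pct_days_covered == 100.0
        assert not snap.gap_gt30
        assert snap.avg_selfreport == 1.0
        assert snap.any_poor_selfreport is False
        assert snap.pct_visits_on_or_before == 100.0
        assert snap.pct_visits_before_exhaustion == 100.0

    def test_two_level_scale_blanks_selfreport_only(self, small_cohort):
        rec = make_patient("P1", selfreport_scale="two_level")
        snap = snapshot_at(rec, small_cohort.visits["P1"],
                           small_cohort.dispensings["P1"],
                           D0 + timedelta(days=180))
        assert snap.avg_selfreport is None
        assert snap.any_imperfect_selfreport is None
        assert snap.pct_days_covered == 100.0

    def test_snapshot_beyond_horizon_refused(self, small_cohort):
        rec = make_patient("P1", data_collection_date=D0 + timedelta(days=100))
        with pytest.raises(ValueError, match="horizon"):
            snapshot_at(rec, small_cohort.visits["P1"],
                        small_cohort.dispensings["P1"],
                        D0 + timedelta(days=180))

    def test_snapshot_before_first_visit_refused(self, small_cohort):
        rec = small_cohort.patients["P2"]
        with pytest.raises(ValueError, match="first recorded visit"):
            snapshot_at(rec, small_cohort.visits["P2"][1:],
                        small_cohort.dispensings["P2"],
                        D0 + timedelta(days=30))

    @pytest.mark.parametrize("days,expected", [
        ([150, 200], 200),    # |150-180|=30 > |200-180|=20
        ([160, 200], 160),    # equidistant: earlier wins
        ([90], 90),
    ])
    def test_index_visit_selection(self, days, expected):
        visits = [visit(d) for d in days]
        assert select_index_visit(visits, D0) == D0 + timedelta(days=expected)


class TestCoverageBands:
    @pytest.mark.parametrize("pct,scheme,label", [
        (95.0, "table2", "95% to <100%"),
        (100.0, "model", "100%"),
        (79.999, "model", "<80%"),
        (80.0, "model", "80% to <90%"),
        (84.9, "table2", "80% to <85%"),
        (99.999, "table2", "95% to <100%"),
    ])
    def test_band_edges(self, pct, scheme, label):
        assert categorize_coverage(pct, scheme) == label

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            categorize_coverage(100.1, "model")
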
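"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: coverage is a literal
per-day pool walk, the gap is a run-length scan, exhaustion timeliness is
direct date arithmetic, and tau-b is exhaustive pair counting.
"""

from __future__ import annotations

import math


def naive_daily_coverage(dispensings: list[tuple[int, int]], window: int) -> list[bool]:
    """Day-by-day supply pool: day d covered iff pool (after any same-day
    dispensing) is positive; one unit consumed per covered day."""
    by_day: dict[int, int] = {}
    for day, supply in dispensings:
        if 0 <= day < window:
            by_day[day] = by_day.get(day, 0) + supply
    covered = []
    pool = 0
    for day in range(window):
        pool += by_day.get(day, 0)
        if pool > 0:
            covered.append(True)
            pool -= 1
        else:
            covered.append(False)
    return covered


def naive_longest_gap(covered: list[bool]) -> int:
    best = run = 0
    for c in covered:
        run = 0 if c else run + 1
        best = max(best, run)
    return best


def naive_exhaustion_timeliness(
    visit_days: list[int], dispensings: list[tuple[int, int]]
) -> float | None:
    """Percent of visits (after the first) occurring on or before the
    previous visit's dispensing exhaustion date; no carryover."""
    supply_by_day: dict[int, int] = {}
    for day, supply in dispensings:
        if day in supply_by_day:
            supply_by_day[day] = min(supply_by_day[day], supply)
        else:
            supply_by_day[day] = supply
    days = sorted(visit_days)
    n = timely = 0
    for prev, cur in zip(days, days[1:]):
        if prev not in supply_by_day:
            continue
        n += 1
        if cur <= prev + supply_by_day[prev]:
            timely += 1
    if n == 0:
        return None
    return 100.0 * timely / n


def brute_force_tau_b(x: list[float], y: list[float]) -> float | None:
    """Tau-b by exhaustive concordant/discordant pair counting."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) // 2
    n1 = n0 - discordant - concordant - ties_y   # pairs tied on x (incl. both)
    n2 = n0 - discordant - concordant - ties_x   # pairs tied on y (incl. both)
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    if denom == 0:
        return None
    return (concordant - discordant) / denom
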
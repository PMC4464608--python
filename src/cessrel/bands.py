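"""Shared categorical bands, baseline cut points and the year clock.

All continuous time is measured in days; calendar years are exactly 365
days long so that day-partition arithmetic in the life-grid round trip
is exact.  Day 0 is 1 January of the year of injection onset.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Sequence

YEAR = 365.0

# Current-age bands; reference band is 20-25.  Left-closed: an exact
# boundary age belongs to the older band.
AGE_BOUNDS = (20.0, 26.0, 31.0, 36.0)
AGE_LABELS = ("<20", "20-25", "26-30", "31-35", "35+")
AGE_REF = "20-25"

# Previous-event-count bands (events of the same process before the
# current episode); reference band is "0".
PREV_LABELS = ("0", "1-2", "3-4", "5-9", "10+")
PREV_REF = "0"

OST_LEVELS = ("off", "on", "unknown")

# Default piecewise-constant baseline cut points, in gap-time days.
# Cessation: <=3 d, (3,7] d, (1,12] wk, (3,12] mo, >1 y.
CESSATION_CUTS = (3.0, 7.0, 84.0, 365.0)
# Relapse: <=2 mo, (2,12] mo, (1,2] y, >2 y (2 months = 61 days).
RELAPSE_CUTS = (61.0, 365.0, 730.0)

CESSATION = "cessation"
RELAPSE = "relapse"

ONSET_ERA_SPLIT = 1986  # HIV testing became widely available


def age_band(age_years: float) -> str:
    """Band label for a current age in years."""
    # +tolerance: a birthday split lands exactly on the boundary and the
    # tie goes to the older band (left-closed bands)
    return AGE_LABELS[bisect_right(AGE_BOUNDS, age_years + 1e-9)]


def prev_event_band(n_previous: int) -> str:
    """Band label for the number of previous same-process events."""
    if n_previous < 0:
        raise ValueError(f"negative previous-event count: {n_previous}")
    if n_previous == 0:
        return "0"
    if n_previous <= 2:
        return "1-2"
    if n_previous <= 4:
        return "3-4"
    if n_previous <= 9:
        return "5-9"
    return "10+"


def baseline_interval_index(gap_days: float, cuts: Sequence[float]) -> int:
    """Index of the baseline-hazard interval containing gap time ``gap_days``.

    Intervals are right-closed: cut points (c1 < c2 < ...) define
    [0, c1], (c1, c2], ..., (ck, inf).  Row start times sit on interval
    interiors so ``bisect`` on the left endpoint is what we want.
    """
    from bisect import bisect_left

    return bisect_left(list(cuts), gap_days + 1e-12)


def baseline_interval_labels(cuts: Sequence[float]) -> list[str]:
    labels = []
    prev = 0.0
    for c in cuts:
        labels.append(f"({prev:g},{c:g}]d" if prev else f"<={c:g}d")
        prev = c
    labels.append(f">{prev:g}d")
    return labels


def default_cuts(process: str) -> tuple[float, ...]:
    if process == CESSATION:
        return CESSATION_CUTS
    if process == RELAPSE:
        return RELAPSE_CUTS
    raise ValueError(f"unknown process {process!r}")
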
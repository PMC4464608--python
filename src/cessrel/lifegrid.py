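"""Impute continuous-time cessation/relapse events from annual life grids.

A life grid is a retrospective per-calendar-year questionnaire record:
for each year since injection onset, whether the person injected, how
many distinct non-injection periods of at least 3 months occurred, and
the number of days spent injecting.  The imputation algorithm converts
these annual counts into a continuous alternating sequence of injecting
and non-injecting episodes while *minimizing* the number of transitions:
processing years chronologically, each year's 1-3 non-injection periods
are assigned to the beginning, middle or end of the year (a single
period goes to the end if the previous year finished injecting,
otherwise to the beginning so it can merge with the previous year's
trailing period), the year's non-injecting days are split equally among
its periods, and a period flush to a year boundary fuses with a period
flush to the other side of the same boundary into one continuous
non-injection episode.

Times are in days since 1 January of the onset year; years are 365 days.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from cessrel.bands import YEAR

logger = logging.getLogger(__name__)

INJECTING = "injecting"
NON_INJECTING = "non-injecting"

#: terminal-event kinds
CESSATION_EVENT = "cessation"
RELAPSE_EVENT = "relapse"
CENSORED = "censored"

_EPS = 1e-9


@dataclass(frozen=True)
class LifeGridRow:
    year: int
    injected: int            # 0/1: any injecting that year
    n_periods: int           # distinct >=3-month non-injection periods
    days_injecting: float    # days injecting in that year


@dataclass
class LifeGrid:
    person_id: str
    onset_year: int
    rows: list[LifeGridRow]
    interview_day: float     # days since 1 Jan of onset year (exclusive end)

    def validate(self) -> None:
        if not self.rows:
            raise ValueError(f"{self.person_id}: empty life grid")
        if self.interview_day <= 0:
            raise ValueError(f"{self.person_id}: career ends before onset year")
        years = [r.year for r in self.rows]
        if years != list(range(self.onset_year, self.onset_year + len(years))):
            raise ValueError(f"{self.person_id}: years not contiguous from onset")
        for r in self.rows:
            length = self._year_length(r.year)
            if not -_EPS <= r.days_injecting <= length + _EPS:
                raise ValueError(
                    f"{self.person_id}/{r.year}: days_injecting outside [0, {length}]"
                )
            if r.injected == 0 and r.days_injecting > _EPS:
                raise ValueError(
                    f"{self.person_id}/{r.year}: injected=0 but days_injecting>0"
                )
            if r.n_periods < 0:
                raise ValueError(f"{self.person_id}/{r.year}: negative period count")

    def _year_start(self, year: int) -> float:
        return (year - self.onset_year) * YEAR

    def _year_length(self, year: int) -> float:
        return min(self._year_start(year) + YEAR, self.interview_day) - self._year_start(year)


@dataclass(frozen=True)
class PeriodPlacement:
    """Slot assignment for one calendar year's non-injection periods."""

    year: int
    slots: tuple[str, ...]       # subset of ("beginning", "middle", "end")
    days_per_period: float

    @property
    def n_placed(self) -> int:
        return len(self.slots)


@dataclass(frozen=True)
class Episode:
    """One maximal injecting or non-injecting period in continuous time.

    ``start_day``/``end_day`` are half-open [start, end) in days since
    1 January of the onset year; ``index`` is 1-based within episodes of
    the same kind.
    """

    person_id: str
    kind: str                    # INJECTING or NON_INJECTING
    index: int
    start_day: float
    end_day: float
    terminal: str                # CESSATION_EVENT / RELAPSE_EVENT / CENSORED

    @property
    def length(self) -> float:
        return self.end_day - self.start_day


@dataclass
class ImputationWarnings:
    clamped_periods: int = 0
    inconsistent_rows: int = 0
    zero_length_periods: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "clamped_periods": self.clamped_periods,
            "inconsistent_rows": self.inconsistent_rows,
            "zero_length_periods": self.zero_length_periods,
        }


def _effective_row(
    grid: LifeGrid, row: LifeGridRow, warn: ImputationWarnings
) -> tuple[int, float]:
    """Return (n periods to place, total non-injecting days) for a year.

    Normalizes the two inconsistent cases: a fully non-injecting year is
    one period covering the year regardless of the reported count, and a
    year reported injected with no qualifying period has its unaccounted
    days treated as injecting (sub-3-month abstinences were never
    elicited, so missing days are not evidence of cessation).
    """
    length = grid._year_length(row.year)
    if row.injected == 0:
        return 1, length
    n = row.n_periods
    noninj = length - row.days_injecting
    if n == 0:
        if noninj > _EPS:
            warn.inconsistent_rows += 1
            logger.warning(
                "%s/%d: injected=1 with %d unaccounted days but no reported "
                "periods; treating them as injecting",
                grid.person_id, row.year, round(noninj),
            )
        return 0, 0.0
    if noninj <= _EPS:
        warn.zero_length_periods += 1
        logger.warning(
            "%s/%d: %d periods reported but zero non-injecting days; dropped",
            grid.person_id, row.year, n,
        )
        return 0, 0.0
    if n > 3:
        warn.clamped_periods += 1
        logger.warning(
            "%s/%d: %d non-injection periods reported; clamping to 3",
            grid.person_id, row.year, n,
        )
        n = 3
    return n, noninj


def assign_period_positions(
    grid: LifeGrid, warnings: ImputationWarnings | None = None
) -> list[PeriodPlacement]:
    """Assign each year's non-injection periods to year slots.

    Years are processed chronologically.  One period goes to the end of
    the year if the preceding year finished with injecting, else to the
    beginning (enabling a cross-year merge); two periods occupy
    beginning+end; three occupy beginning+middle+end.  A fully
    non-injecting year counts as a single period spanning the year.
    """
    grid.validate()
    warn = warnings if warnings is not None else ImputationWarnings()
    placements: list[PeriodPlacement] = []
    prev_ends_noninjecting = False  # career starts with injection
    for row in grid.rows:
        n, noninj = _effective_row(grid, row, warn)
        length = grid._year_length(row.year)
        if n == 0:
            placements.append(PeriodPlacement(row.year, (), 0.0))
            prev_ends_noninjecting = False
            continue
        d = noninj / n
        if n == 1:
            slots = ("beginning",) if prev_ends_noninjecting else ("end",)
        elif n == 2:
            slots = ("beginning", "end")
        else:
            slots = ("beginning", "middle", "end")
        placements.append(PeriodPlacement(row.year, slots, d))
        # year ends non-injecting iff a period is flush to its end
        prev_ends_noninjecting = "end" in slots or d >= length - _EPS
    return placements


def _slot_interval(
    slot: str, year_start: float, year_end: float, d: float
) -> tuple[float, float]:
    if slot == "beginning":
        return (year_start, min(year_start + d, year_end))
    if slot == "end":
        return (max(year_end - d, year_start), year_end)
    # middle: centred on the year midpoint, shifted minimally so it
    # cannot overlap the beginning/end slots
    mid = (year_start + year_end) / 2.0
    lo, hi = mid - d / 2.0, mid + d / 2.0
    if lo < year_start + d:
        shift = year_start + d - lo
        lo, hi = lo + shift, hi + shift
    if hi > year_end - d:
        shift = hi - (year_end - d)
        lo, hi = lo - shift, hi - shift
    return (lo, hi)


def impute_event_times(
    grid: LifeGrid,
    placements: list[PeriodPlacement] | None = None,
    warnings: ImputationWarnings | None = None,
) -> list[Episode]:
    """Impute the continuous episode sequence from an annual life grid.

    Returns alternating injecting / non-injecting episodes covering
    [0, interview_day) with no gaps; the first episode is injecting
    (zero-length if a non-injection period starts at onset day 0, so
    that alternation and episode indexing are preserved).  A period
    flush to the end of one year merges with a period flush to the start
    of the next into a single non-injection episode.
    """
    warn = warnings if warnings is not None else ImputationWarnings()
    if placements is None:
        placements = assign_period_positions(grid, warnings=warn)

    # build non-injection intervals in absolute day coordinates
    intervals: list[tuple[float, float]] = []
    for pl in placements:
        ys = grid._year_start(pl.year)
        ye = ys + grid._year_length(pl.year)
        for slot in pl.slots:
            iv = _slot_interval(slot, ys, ye, pl.days_per_period)
            if iv[1] - iv[0] > _EPS:
                intervals.append(iv)
    intervals.sort()

    # merge across year boundaries only: two reported periods in the
    # same year remain distinct even if imputed flush to each other
    def at_year_boundary(x: float) -> bool:
        r = x % YEAR
        return min(r, YEAR - r) <= 1e-6

    merged: list[list[float]] = []
    for s, e in intervals:
        if merged and s - merged[-1][1] <= _EPS and at_year_boundary(s):
            merged[-1][1] = e
        else:
            merged.append([s, e])

    episodes: list[Episode] = []
    t = 0.0
    n_inj = n_non = 0
    end = grid.interview_day
    for s, e in merged:
        e = min(e, end)
        n_inj += 1
        episodes.append(
            Episode(grid.person_id, INJECTING, n_inj, t, s, CESSATION_EVENT)
        )
        n_non += 1
        terminal = CENSORED if e >= end - _EPS else RELAPSE_EVENT
        episodes.append(Episode(grid.person_id, NON_INJECTING, n_non, s, e, terminal))
        t = e
    if t < end - _EPS or not episodes:
        n_inj += 1
        episodes.append(Episode(grid.person_id, INJECTING, n_inj, t, end, CENSORED))
    return episodes


def count_transitions(episodes: Sequence[Episode]) -> tuple[int, int]:
    """Counts of (cessations, relapses) among episode terminal events."""
    n_cess = sum(1 for ep in episodes if ep.terminal == CESSATION_EVENT)
    n_rel = sum(1 for ep in episodes if ep.terminal == RELAPSE_EVENT)
    return n_cess, n_rel


# ---------------------------------------------------------------------------
# tabular I/O

LIFEGRID_COLUMNS = ["person_id", "year", "injected", "n_noninjection_periods", "days_injecting"]
EPISODE_COLUMNS = ["person_id", "kind", "index", "start_day", "end_day", "terminal"]


def grids_to_frame(grids: Iterable[LifeGrid]) -> pd.DataFrame:
    recs = []
    for g in grids:
        for r in g.rows:
            recs.append((g.person_id, r.year, r.injected, r.n_periods, r.days_injecting))
    return pd.DataFrame(recs, columns=LIFEGRID_COLUMNS)


def grids_from_frame(
    df: pd.DataFrame, interview_days: dict[str, float]
) -> list[LifeGrid]:
    """Rebuild LifeGrid objects from the long table written by `grids_to_frame`.

    ``interview_days`` maps person_id to the censoring day (days since
    1 Jan of that person's onset year).
    """
    grids = []
    for pid, sub in df.groupby("person_id", sort=True):
        sub = sub.sort_values("year")
        rows = [
            LifeGridRow(int(r.year), int(r.injected), int(r.n_noninjection_periods),
                        float(r.days_injecting))
            for r in sub.itertuples()
        ]
        onset_year = rows[0].year
        iv = interview_days.get(str(pid))
        if iv is None:
            iv = len(rows) * YEAR
        grids.append(LifeGrid(str(pid), onset_year, rows, float(iv)))
    return grids


def episodes_to_frame(episodes: Iterable[Episode]) -> pd.DataFrame:
    recs = [
        (ep.person_id, ep.kind, ep.index, ep.start_day, ep.end_day, ep.terminal)
        for ep in episodes
    ]
    return pd.DataFrame(recs, columns=EPISODE_COLUMNS)


def episodes_from_frame(df: pd.DataFrame) -> dict[str, list[Episode]]:
    out: dict[str, list[Episode]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.person_id), []).append(
            Episode(str(r.person_id), r.kind, int(r.index),
                    float(r.start_day), float(r.end_day), r.terminal)
        )
    for eps in out.values():
        eps.sort(key=lambda ep: ep.start_day)
    return out
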
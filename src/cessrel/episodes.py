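"""Expand episodes into counting-process risk-set rows in gap time.

Each at-risk episode (injecting episodes for the cessation process,
non-injecting episodes for relapse) is cut into contiguous slices over
which the baseline-hazard interval and every covariate are constant:
splits occur at the baseline cut points (gap time), at OST status
changes and at birthdays crossing a current-age band boundary (absolute
time).  Exposures sum exactly to the episode length and the event
indicator sits on the final slice only.

`apply_within_between` implements the between/within decomposition used
to guard against confounding by cluster: the time-on-OST fraction of
the person's whole follow-up enters as a between-person regressor, and
the deviation of current status from that fraction as a within-person
regressor.  Constraining the two coefficients to be equal recovers the
undecomposed model exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from cessrel import bands
from cessrel.bands import YEAR, CESSATION, RELAPSE, age_band, prev_event_band
from cessrel.lifegrid import CENSORED, CESSATION_EVENT, INJECTING, NON_INJECTING, RELAPSE_EVENT, Episode

_EPS = 1e-9

RISKSET_COLUMNS = [
    "person_id", "process", "episode_index", "t0", "t1", "exposure", "event",
    "baseline_interval", "sex", "onset_age_band", "onset_era",
    "current_age_band", "ost_status", "prev_event_band", "decade",
]


@dataclass
class CovariateProfile:
    """Per-person covariates and the OST interval history.

    ``birth_day`` is in days since 1 January of the onset year (negative
    for anyone born before onset, i.e. everyone); OST intervals must
    partition [0, censor_day) — time outside case-note coverage should
    already be coded "unknown".
    """

    person_id: str
    sex: str
    onset_year: int
    birth_day: float
    censor_day: float
    ost_intervals: list[tuple[float, float, str]] = field(default_factory=list)

    @property
    def onset_age(self) -> float:
        return -self.birth_day / YEAR

    @property
    def onset_age_band(self) -> str:
        return "20+" if self.onset_age >= 20.0 else "12-19"

    @property
    def onset_era(self) -> str:
        return ">=1986" if self.onset_year >= bands.ONSET_ERA_SPLIT else "<1986"

    def validate(self) -> None:
        if not self.ost_intervals:
            raise ValueError(f"{self.person_id}: no OST intervals")
        ivs = sorted(self.ost_intervals)
        if ivs[0][0] > _EPS or ivs[-1][1] < self.censor_day - _EPS:
            raise ValueError(f"{self.person_id}: OST intervals do not cover follow-up")
        for (s0, e0, _), (s1, e1, _) in zip(ivs[:-1], ivs[1:]):
            if abs(e0 - s1) > _EPS:
                raise ValueError(f"{self.person_id}: gap/overlap in OST intervals at {e0}")
        for s, e, st in ivs:
            if st not in bands.OST_LEVELS:
                raise ValueError(f"{self.person_id}: unknown OST status {st!r}")

    def ost_status_at(self, t: float) -> str:
        for s, e, st in self.ost_intervals:
            if s - _EPS <= t < e - _EPS:
                return st
        if self.ost_intervals and t >= self.ost_intervals[-1][1] - _EPS:
            return self.ost_intervals[-1][2]
        raise ValueError(f"{self.person_id}: no OST status at day {t}")


@dataclass(frozen=True)
class OstFractions:
    """Fractions of total follow-up spent on OST and with unknown status."""

    person_id: str
    frac_on: float
    frac_unknown: float


def compute_ost_fractions(
    profile: CovariateProfile, at_risk_spans: Sequence[tuple[float, float]] | None = None
) -> OstFractions:
    """Time-on-OST and unknown-OST fractions of the person's follow-up.

    By default "follow-up" is onset to interview; pass ``at_risk_spans``
    to restrict to at-risk time for one process instead.
    """
    profile.validate()
    spans = [(0.0, profile.censor_day)] if at_risk_spans is None else list(at_risk_spans)
    total = on = unknown = 0.0
    for lo, hi in spans:
        for s, e, st in profile.ost_intervals:
            ov = min(e, hi) - max(s, lo)
            if ov <= 0:
                continue
            total += ov
            if st == "on":
                on += ov
            elif st == "unknown":
                unknown += ov
    if total <= 0:
        raise ValueError(f"{profile.person_id}: zero follow-up")
    return OstFractions(profile.person_id, on / total, unknown / total)


def assign_prev_event_band(episodes: Sequence[Episode], process: str) -> dict[int, str]:
    """Map episode index j -> previous-event band for one process.

    The j-th at-risk episode has j-1 prior terminal events of the same
    process (alternation guarantees every earlier same-kind episode
    ended in that event).
    """
    kind = INJECTING if process == CESSATION else NON_INJECTING
    return {ep.index: prev_event_band(ep.index - 1)
            for ep in episodes if ep.kind == kind}


def _decade_label(year: float) -> str:
    return f"{int(year) // 10 * 10}s"


def build_gap_time_records(
    episodes: Sequence[Episode],
    profile: CovariateProfile,
    cuts: Sequence[float] | None = None,
    process: str = CESSATION,
    include_decade: bool = False,
) -> pd.DataFrame:
    """Counting-process rows for one person's at-risk episodes.

    Returns a DataFrame with one row per (episode x constant-covariate x
    constant-baseline) slice; gap time t0/t1 is measured from the start
    of the episode.  Zero-length episodes (an imputed cessation at onset
    day 0) produce no rows but still advance the previous-event count;
    negative-length episodes are an error.
    """
    if process not in (CESSATION, RELAPSE):
        raise ValueError(f"unknown process {process!r}")
    profile.validate()
    if cuts is None:
        cuts = bands.default_cuts(process)
    kind = INJECTING if process == CESSATION else NON_INJECTING
    event_terminal = CESSATION_EVENT if process == CESSATION else RELAPSE_EVENT
    at_risk = [ep for ep in episodes if ep.kind == kind]

    records = []
    for ep in at_risk:
        if ep.length < -_EPS:
            raise ValueError(f"{profile.person_id}: negative-length episode {ep}")
        if ep.length <= _EPS:
            continue
        prev_band = prev_event_band(ep.index - 1)
        length = ep.length
        splits = {0.0, length}
        splits.update(c for c in cuts if 0.0 < c < length - _EPS)
        for s, e, _ in profile.ost_intervals:
            for x in (s, e):
                g = x - ep.start_day
                if _EPS < g < length - _EPS:
                    splits.add(g)
        for a in bands.AGE_BOUNDS:
            g = (a * YEAR + profile.birth_day) - ep.start_day
            if _EPS < g < length - _EPS:
                splits.add(g)
        if include_decade:
            first_year = profile.onset_year + int(ep.start_day // YEAR)
            dec_start = first_year // 10 * 10
            for y in range(dec_start + 10, 3000, 10):
                g = (y - profile.onset_year) * YEAR - ep.start_day
                if g >= length - _EPS:
                    break
                if g > _EPS:
                    splits.add(g)
        pts = sorted(splits)
        for t0, t1 in zip(pts[:-1], pts[1:]):
            abs0 = ep.start_day + t0
            age = (abs0 - profile.birth_day) / YEAR
            is_last = t1 >= length - _EPS
            records.append((
                profile.person_id, process, ep.index, t0, t1, t1 - t0,
                int(is_last and ep.terminal == event_terminal),
                bands.baseline_interval_index(t0, cuts),
                profile.sex, profile.onset_age_band, profile.onset_era,
                age_band(age), profile.ost_status_at(abs0), prev_band,
                _decade_label(profile.onset_year + abs0 / YEAR) if include_decade else "",
            ))
    return pd.DataFrame(records, columns=RISKSET_COLUMNS)


def apply_within_between(rows: pd.DataFrame, fractions: dict[str, OstFractions]) -> pd.DataFrame:
    """Add decomposed OST regressors to risk-set rows.

    ost_on_between is the person's follow-up fraction on OST (constant
    within person); ost_on_within is I(currently on) minus that
    fraction; analogously for unknown status.
    """
    missing = set(rows["person_id"].unique()) - set(fractions)
    if missing:
        raise ValueError(f"no OST fractions for persons: {sorted(missing)[:5]}")
    out = rows.copy()
    frac_on = rows["person_id"].map(lambda p: fractions[p].frac_on).to_numpy()
    frac_na = rows["person_id"].map(lambda p: fractions[p].frac_unknown).to_numpy()
    on = (rows["ost_status"] == "on").to_numpy(float)
    na = (rows["ost_status"] == "unknown").to_numpy(float)
    out["ost_on_between"] = frac_on
    out["ost_on_within"] = on - frac_on
    out["ost_na_between"] = frac_na
    out["ost_na_within"] = na - frac_na
    return out


def profile_from_career(career) -> CovariateProfile:
    """CovariateProfile for a simulated TrueCareer."""
    return CovariateProfile(
        person_id=career.person_id,
        sex=career.sex,
        onset_year=career.onset_year,
        birth_day=-career.onset_age * YEAR,
        censor_day=career.censor_day,
        ost_intervals=list(career.ost_intervals),
    )


def build_cohort_records(
    episodes_by_person: dict[str, list[Episode]],
    profiles: dict[str, CovariateProfile],
    process: str,
    cuts: Sequence[float] | None = None,
    include_decade: bool = False,
    decompose_ost: bool = True,
) -> pd.DataFrame:
    """Risk-set rows for a whole cohort, with decomposed OST regressors."""
    frames = []
    fractions = {}
    for pid, eps in episodes_by_person.items():
        prof = profiles[pid]
        frames.append(build_gap_time_records(eps, prof, cuts, process, include_decade))
        if decompose_ost:
            fractions[pid] = compute_ost_fractions(prof)
    rows = pd.concat([f for f in frames if len(f)], ignore_index=True)
    if decompose_ost:
        rows = apply_within_between(rows, fractions)
    return rows
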
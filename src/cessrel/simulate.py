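"""Generate synthetic injecting careers and coarsen them to life grids.

A career is an alternating renewal process: injecting episodes end in
cessation with a piecewise-constant gap-time hazard, non-injecting
episodes end in relapse with their own piecewise-constant hazard, and
both hazards are multiplied by exp(x'beta + u) where x collects the
time-constant covariates (sex, onset age band, onset era) and the
time-varying ones (current age band, current OST status, number of
previous same-process events) and u is the person's normal random
effect for that process.  OST status follows a two-state continuous-time
Markov chain whose sojourns are independently masked to "unknown".

`coarsen_to_lifegrid` degrades the continuous truth to the annual
questionnaire format: per calendar year, an injected flag, the count of
distinct qualifying (>= 3 month) non-injection periods, and days spent
injecting, with sub-threshold abstinences absorbed into injecting time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cessrel import bands
from cessrel.bands import YEAR, CESSATION, RELAPSE, age_band, prev_event_band
from cessrel.lifegrid import (
    CENSORED,
    CESSATION_EVENT,
    INJECTING,
    NON_INJECTING,
    RELAPSE_EVENT,
    Episode,
    LifeGrid,
    LifeGridRow,
)
from cessrel.params import CareerParams

_AGE_KEY = {"<20": "age_lt20", "20-25": None, "26-30": "age_26_30",
            "31-35": "age_31_35", "35+": "age_36plus"}
_PREV_KEY = {"0": None, "1-2": "prev_1_2", "3-4": "prev_3_4",
             "5-9": "prev_5_9", "10+": "prev_10plus"}
_OST_KEY = {"off": None, "on": "ost_on", "unknown": "ost_unknown"}


@dataclass
class TrueCareer:
    """Ground-truth career: continuous episodes, OST history and frailties.

    All times are days since 1 January of the onset year; the first
    injection happens at day 0.
    """

    person_id: str
    sex: str                      # "male" / "female"
    onset_year: int
    onset_age: float              # age in years at day 0
    frailty_pair: tuple[float, float]   # (u_cessation, u_relapse)
    censor_day: float             # interview day
    episodes: list[Episode]
    ost_intervals: list[tuple[float, float, str]]

    @property
    def birth_day(self) -> float:
        return -self.onset_age * YEAR


def _log_hr(beta: dict[str, float], sex: str, onset_age: float, onset_year: int,
            age: float, ost_status: str, prev_count: int) -> float:
    lp = 0.0
    if sex == "female":
        lp += beta.get("female", 0.0)
    if onset_age >= 20.0:
        lp += beta.get("onset_20plus", 0.0)
    if onset_year >= bands.ONSET_ERA_SPLIT:
        lp += beta.get("onset_post1986", 0.0)
    k = _AGE_KEY[age_band(age)]
    if k:
        lp += beta.get(k, 0.0)
    k = _OST_KEY[ost_status]
    if k:
        lp += beta.get(k, 0.0)
    k = _PREV_KEY[prev_event_band(prev_count)]
    if k:
        lp += beta.get(k, 0.0)
    return lp


def _simulate_ost(params: CareerParams, censor_day: float,
                  rng: np.random.Generator) -> list[tuple[float, float, str]]:
    """Two-state Markov chain with per-sojourn masking to 'unknown'."""
    t = 0.0
    status = "off"
    raw: list[tuple[float, float, str]] = []
    while t < censor_day:
        rate = params.ost_on_rate if status == "off" else params.ost_off_rate
        dur = rng.exponential(1.0 / rate)
        end = min(t + dur, censor_day)
        obs = "unknown" if rng.random() < params.ost_unknown_prob else status
        raw.append((t, end, obs))
        t = end
        status = "on" if status == "off" else "off"
    merged: list[tuple[float, float, str]] = []
    for s, e, st in raw:
        if merged and merged[-1][2] == st:
            merged[-1] = (merged[-1][0], e, st)
        else:
            merged.append((s, e, st))
    return merged


def _ost_status_at(ost: Sequence[tuple[float, float, str]], t: float) -> str:
    for s, e, st in ost:
        if s <= t < e:
            return st
    return ost[-1][2] if ost else "unknown"


def _draw_gap(
    process: str,
    t_start: float,
    max_gap: float,
    params: CareerParams,
    sex: str,
    onset_age: float,
    onset_year: int,
    prev_count: int,
    u: float,
    ost: Sequence[tuple[float, float, str]],
    rng: np.random.Generator,
) -> float | None:
    """Draw one gap time by inverting the piecewise-constant cumulative hazard.

    Returns the gap in days, or None if the episode survives past
    ``max_gap`` (censoring).  The hazard is constant between breakpoints
    collected from the baseline cut points (gap time) and the change
    times of OST status and the current-age band (absolute time).
    """
    if process == CESSATION:
        cuts, rates, beta = params.cessation_cuts, params.cessation_rates, params.beta_cessation
    else:
        cuts, rates, beta = params.relapse_cuts, params.relapse_rates, params.beta_relapse

    breaks = {0.0, max_gap}
    breaks.update(c for c in cuts if 0.0 < c < max_gap)
    for s, e, _ in ost:
        for x in (s, e):
            g = x - t_start
            if 0.0 < g < max_gap:
                breaks.add(g)
    for a in bands.AGE_BOUNDS:
        g = (a - onset_age) * YEAR - t_start
        if 0.0 < g < max_gap:
            breaks.add(g)
    pts = sorted(breaks)

    target = rng.exponential(1.0)
    acc = 0.0
    for lo, hi in zip(pts[:-1], pts[1:]):
        lam = rates[bands.baseline_interval_index(lo, cuts)]
        age = onset_age + (t_start + lo) / YEAR
        ost_status = _ost_status_at(ost, t_start + lo)
        lp = _log_hr(beta, sex, onset_age, onset_year, age, ost_status, prev_count)
        rate = lam * math.exp(lp + u)
        if rate <= 0 or not math.isfinite(rate):
            raise ValueError(f"non-positive or non-finite hazard {rate} for {process}")
        seg = hi - lo
        if acc + rate * seg >= target:
            return lo + (target - acc) / rate
        acc += rate * seg
    return None


def simulate_career(
    params: CareerParams,
    covariates: dict,
    frailty_pair: tuple[float, float],
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> TrueCareer:
    """Simulate one career given its covariates and frailty pair.

    ``covariates`` must provide person_id, sex, onset_year, onset_age
    and censor_day.  Identical inputs and seed give identical output.
    """
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pid = str(covariates["person_id"])
    sex = covariates["sex"]
    onset_year = int(covariates["onset_year"])
    onset_age = float(covariates["onset_age"])
    censor = float(covariates["censor_day"])
    if censor <= 0:
        raise ValueError(f"{pid}: censor_day must be positive")
    u_cess, u_rel = frailty_pair

    ost = _simulate_ost(params, censor, rng)

    episodes: list[Episode] = []
    t = 0.0
    kind = INJECTING
    n_inj = n_non = 0
    while t < censor:
        process = CESSATION if kind == INJECTING else RELAPSE
        prev = n_inj if kind == INJECTING else n_non
        u = u_cess if kind == INJECTING else u_rel
        gap = _draw_gap(process, t, censor - t, params, sex, onset_age,
                        onset_year, prev, u, ost, rng)
        if kind == INJECTING:
            n_inj += 1
            idx = n_inj
        else:
            n_non += 1
            idx = n_non
        if gap is None:
            episodes.append(Episode(pid, kind, idx, t, censor, CENSORED))
            break
        terminal = CESSATION_EVENT if kind == INJECTING else RELAPSE_EVENT
        episodes.append(Episode(pid, kind, idx, t, t + gap, terminal))
        t += gap
        kind = NON_INJECTING if kind == INJECTING else INJECTING

    return TrueCareer(pid, sex, onset_year, onset_age, (u_cess, u_rel),
                      censor, episodes, ost)


def draw_covariates(params: CareerParams, person_id: str,
                    rng: np.random.Generator) -> dict:
    onset_age = rng.uniform(*params.onset_age_range)
    onset_year = int(rng.integers(params.onset_year_range[0],
                                  params.onset_year_range[1] + 1))
    interview_year = int(rng.integers(params.interview_years[0],
                                      params.interview_years[1] + 1))
    censor_day = (interview_year - onset_year) * YEAR + rng.uniform(0.0, YEAR)
    return {
        "person_id": person_id,
        "sex": "female" if rng.random() < params.sex_probability else "male",
        "onset_year": onset_year,
        "onset_age": onset_age,
        "censor_day": censor_day,
    }


def simulate_cohort(
    n: int, params: CareerParams, seed: int | np.random.SeedSequence
) -> list[TrueCareer]:
    """Simulate ``n`` careers with frailty pairs from a bivariate normal.

    One cohort-level seed; per-person streams are derived
    deterministically from it, so the cohort is reproducible and
    insensitive to how many persons are drawn after a given one.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    params.validate()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    frailty_ss, *person_ss = ss.spawn(n + 1)
    frng = np.random.default_rng(frailty_ss)
    cov = np.array([
        [params.sigma2_cess,
         params.rho * math.sqrt(params.sigma2_cess * params.sigma2_rel)],
        [params.rho * math.sqrt(params.sigma2_cess * params.sigma2_rel),
         params.sigma2_rel],
    ])
    if params.sigma2_cess == 0 and params.sigma2_rel == 0:
        frailties = np.zeros((n, 2))
    else:
        frailties = frng.multivariate_normal([0.0, 0.0], cov, size=n, method="svd")
    width = len(str(n))
    careers = []
    for i in range(n):
        prng = np.random.default_rng(person_ss[i])
        covs = draw_covariates(params, f"p{i + 1:0{width}d}", prng)
        careers.append(simulate_career(params, covs, tuple(frailties[i]), prng))
    return careers


def coarsen_to_lifegrid(
    career: TrueCareer,
    min_period_days: float | None = None,
    rule: str = "total",
) -> LifeGrid:
    """Coarsen a continuous career to the annual life-grid report.

    A non-injection episode qualifies for reporting in a year if it
    overlaps that year by at least one day and — under the default
    ``rule="total"`` — its *total* length is at least the elicitation
    floor (90 days); ``rule="within_year"`` instead requires at least
    the floor amount *inside* the year.  Non-qualifying abstinences are
    absorbed into injecting time, mimicking that sub-3-month abstinences
    were never elicited.
    """
    if rule not in ("total", "within_year"):
        raise ValueError(f"unknown elicitation rule {rule!r}")
    floor = 90.0 if min_period_days is None else float(min_period_days)
    if career.censor_day <= 0:
        raise ValueError(f"{career.person_id}: career ends before onset year")
    noninj = [ep for ep in career.episodes if ep.kind == NON_INJECTING]
    n_years = int(math.ceil((career.censor_day - 1e-9) / YEAR))
    rows = []
    for k in range(n_years):
        ys = k * YEAR
        ye = min(ys + YEAR, career.censor_day)
        length = ye - ys
        n_periods = 0
        noninj_days = 0.0
        for ep in noninj:
            ov = min(ep.end_day, ye) - max(ep.start_day, ys)
            if ov <= 1e-9:
                continue
            qualifies = (ep.length >= floor) if rule == "total" else (ov >= floor)
            if qualifies:
                n_periods += 1
                noninj_days += ov
        days_injecting = max(length - noninj_days, 0.0)
        injected = 1 if days_injecting > 1e-9 else 0
        rows.append(LifeGridRow(career.onset_year + k, injected, n_periods,
                                days_injecting if injected else 0.0))
    return LifeGrid(career.person_id, career.onset_year, rows, career.censor_day)


# ---------------------------------------------------------------------------
# tabular export of a simulated cohort

COVARIATE_COLUMNS = ["person_id", "sex", "birth_year", "onset_year", "censor_day"]
OST_COLUMNS = ["person_id", "start_day", "end_day", "status"]


def careers_to_tables(
    careers: Iterable[TrueCareer], params: CareerParams | None = None
) -> dict[str, pd.DataFrame]:
    """Long tables for a cohort: life grids, covariates, OST, true episodes."""
    from cessrel.lifegrid import episodes_to_frame, grids_to_frame

    careers = list(careers)
    floor = params.min_period_days if params is not None else None
    grids = [coarsen_to_lifegrid(c, min_period_days=floor) for c in careers]
    cov = pd.DataFrame(
        [
            (c.person_id, c.sex, c.onset_year - int(round(c.onset_age)),
             c.onset_year, c.censor_day)
            for c in careers
        ],
        columns=COVARIATE_COLUMNS,
    )
    ost = pd.DataFrame(
        [(c.person_id, s, e, st) for c in careers for (s, e, st) in c.ost_intervals],
        columns=OST_COLUMNS,
    )
    truth = episodes_to_frame([ep for c in careers for ep in c.episodes])
    return {
        "lifegrid": grids_to_frame(grids),
        "covariates": cov,
        "ost": ost,
        "true_episodes": truth,
    }
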
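"""Kaplan-Meier estimation of first-event gap-time distributions.

Product-limit estimator with Greenwood variance and 95% confidence
intervals on the complementary log-log scale, plus quantile readout
(median and IQR) using the convention "smallest time with S(t) <= q".
`first_event_dataset` extracts per-person first-event gap times from an
imputed episode sequence: onset to first cessation for the cessation
process, and first cessation to first relapse (among those who ceased
at least once) for relapse.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from cessrel.bands import CESSATION, RELAPSE, YEAR
from cessrel.lifegrid import CESSATION_EVENT, INJECTING, NON_INJECTING, RELAPSE_EVENT, Episode


@dataclass
class SurvivalCurve:
    """Step-function survival estimate with Greenwood 95% CI."""

    times: np.ndarray          # event times (t=0 included, S=1)
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """S(t): step value at time t (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])

    def quantile(self, q: float) -> float:
        """Smallest time with S(t) <= 1-q; NaN if never reached."""
        target = 1.0 - q
        hit = np.nonzero(self.survival <= target + 1e-12)[0]
        if hit.size == 0:
            return math.nan
        return float(self.times[hit[0]])

    @property
    def median(self) -> float:
        return self.quantile(0.5)

    @property
    def iqr(self) -> tuple[float, float]:
        return (self.quantile(0.25), self.quantile(0.75))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "survival": self.survival,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_risk": self.n_risk,
            "n_events": self.n_events,
        })


def kaplan_meier(
    times: Sequence[float], event_flags: Sequence[int], alpha: float = 0.05
) -> SurvivalCurve:
    """Product-limit estimate with Greenwood cloglog confidence bands."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(event_flags, dtype=int)
    if t.size == 0:
        raise ValueError("empty input")
    if np.any(t < 0):
        raise ValueError("negative times")
    if not np.all(np.isin(d, (0, 1))):
        raise ValueError("event flags must be 0/1")

    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    n = t.size

    event_times = np.unique(t[d == 1])
    surv = [1.0]
    var_sum = [0.0]
    n_risk = [n]
    n_events = [0]
    s = 1.0
    g = 0.0
    for et in event_times:
        at_risk = int(np.sum(t >= et))
        dd = int(np.sum((t == et) & (d == 1)))
        s *= 1.0 - dd / at_risk
        if at_risk > dd:
            g += dd / (at_risk * (at_risk - dd))
        else:
            g = math.inf
        surv.append(s)
        var_sum.append(g)
        n_risk.append(at_risk)
        n_events.append(dd)

    times_out = np.concatenate([[0.0], event_times])
    surv = np.array(surv)
    var_sum = np.array(var_sum)

    z = norm.ppf(1.0 - alpha / 2.0)
    lo = np.empty_like(surv)
    hi = np.empty_like(surv)
    with np.errstate(divide="ignore", invalid="ignore"):
        for i, (si, gi) in enumerate(zip(surv, var_sum)):
            if si <= 0.0:
                lo[i] = hi[i] = 0.0
            elif si >= 1.0 or gi == 0.0:
                lo[i] = hi[i] = si
            elif math.isinf(gi):
                lo[i], hi[i] = 0.0, si
            else:
                # CI on log(-log S); se of cloglog via delta method
                se_cll = math.sqrt(gi) / abs(math.log(si))
                cll = math.log(-math.log(si))
                lo[i] = math.exp(-math.exp(cll + z * se_cll))
                hi[i] = math.exp(-math.exp(cll - z * se_cll))
    return SurvivalCurve(times_out, surv, lo, hi,
                         np.array(n_risk), np.array(n_events))


def first_event_dataset(
    episodes_by_person: dict[str, list[Episode]],
    process: str,
    admit_zero: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-person first-event gap times and event flags for one process.

    Cessation: days from onset to first cessation, censored at interview
    for those who never ceased.  Relapse: length of the first
    non-injection episode among persons with at least one cessation,
    censored if it ran to interview.  With ``admit_zero=False``,
    zero-length first gaps (an imputed cessation on the onset day) are
    excluded rather than entering as time 0.
    """
    times, flags = [], []
    for pid, eps in episodes_by_person.items():
        eps = sorted(eps, key=lambda e: (e.start_day, e.kind == NON_INJECTING))
        if process == CESSATION:
            first_inj = next(ep for ep in eps if ep.kind == INJECTING)
            if first_inj.terminal == CESSATION_EVENT:
                tt, ev = first_inj.length, 1
            else:
                tt, ev = first_inj.end_day - first_inj.start_day, 0
            if first_inj.index != 1:
                raise ValueError(f"{pid}: first injecting episode has index != 1")
        elif process == RELAPSE:
            first_non = next((ep for ep in eps if ep.kind == NON_INJECTING), None)
            if first_non is None:
                continue
            tt, ev = first_non.length, int(first_non.terminal == RELAPSE_EVENT)
        else:
            raise ValueError(f"unknown process {process!r}")
        if tt <= 0 and not admit_zero:
            continue
        times.append(tt)
        flags.append(ev)
    return np.asarray(times, float), np.asarray(flags, int)


def km_summary(curve: SurvivalCurve) -> dict:
    """Headline quantities: 12-month and 5-year event probabilities,
    median and IQR (in years)."""
    med = curve.median
    q25, q75 = curve.iqr
    return {
        "prob_event_12mo": 1.0 - curve.at(YEAR),
        "prob_event_5yr": 1.0 - curve.at(5 * YEAR),
        "median_years": med / YEAR if not math.isnan(med) else None,
        "iqr_low_years": q25 / YEAR if not math.isnan(q25) else None,
        "iqr_high_years": q75 / YEAR if not math.isnan(q75) else None,
    }


def write_km_outputs(curve: SurvivalCurve, csv_path: str, json_path: str) -> None:
    curve.to_frame().to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump(km_summary(curve), fh, indent=2)
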
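"""Shared fixtures: small simulated cohorts and hand-made risk-set rows."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cessrel as cr
from cessrel import episodes as eb
from cessrel import simulate
from cessrel.bands import CESSATION, RELAPSE


def make_row(person_id="p1", process=CESSATION, episode_index=1, t0=0.0, t1=1.0,
             event=0, baseline_interval=0, sex="male", onset_age_band="12-19",
             onset_era="<1986", current_age_band="20-25", ost_status="off",
             prev_event_band="0", decade="", **extra):
    """One hand-made counting-process row (dict for DataFrame assembly)."""
    d = {
        "person_id": person_id, "process": process, "episode_index": episode_index,
        "t0": t0, "t1": t1, "exposure": t1 - t0, "event": event,
        "baseline_interval": baseline_interval, "sex": sex,
        "onset_age_band": onset_age_band, "onset_era": onset_era,
        "current_age_band": current_age_band, "ost_status": ost_status,
        "prev_event_band": prev_event_band, "decade": decade,
    }
    d.update(extra)
    return d


def rows_frame(rows):
    return pd.DataFrame(rows)


def cohort_rows(n, seed, params=None, process=CESSATION, decompose=True):
    """Simulate a cohort and expand its TRUE episodes to risk-set rows."""
    params = params or cr.CareerParams()
    cohort = simulate.simulate_cohort(n, params, seed)
    eps_by = {c.person_id: c.episodes for c in cohort}
    profs = {c.person_id: eb.profile_from_career(c) for c in cohort}
    rows = eb.build_cohort_records(eps_by, profs, process, decompose_ost=decompose)
    return cohort, rows


@pytest.fixture(scope="session")
def default_params():
    return cr.CareerParams()


@pytest.fixture(scope="session")
def small_cohort(default_params):
    """50 simulated careers shared across read-only tests."""
    return simulate.simulate_cohort(50, default_params, seed=424242)


@pytest.fixture(scope="session")
def small_cohort_rows(small_cohort):
    eps_by = {c.person_id: c.episodes for c in small_cohort}
    profs = {c.person_id: eb.profile_from_career(c) for c in small_cohort}
    return {
        CESSATION: eb.build_cohort_records(eps_by, profs, CESSATION),
        RELAPSE: eb.build_cohort_records(eps_by, profs, RELAPSE),
    }
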
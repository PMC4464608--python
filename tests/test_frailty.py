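"""Frailty model: likelihood oracles, closed forms, LR tests, selection."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

import cessrel as cr
from cessrel import episodes as eb
from cessrel import frailty, simulate
from cessrel.bands import CESSATION, RELAPSE
from tests.conftest import cohort_rows, make_row, rows_frame

FLAT = frailty.ModelSpec(process=CESSATION, cuts=(), terms=(), frailty="none")


def test_single_row_exponential_loglik():
    lam, t = 0.02, 37.0
    rows = rows_frame([make_row(t1=t, event=1)])
    ll = frailty.piecewise_exponential_loglik(rows, FLAT, [math.log(lam)])
    assert ll == pytest.approx(math.log(lam) - lam * t, abs=1e-12)


def test_zero_coefficient_covariate_changes_nothing():
    rows = rows_frame([make_row(t1=50.0, event=1, sex="female"),
                       make_row(person_id="p2", t1=20.0)])
    spec0 = frailty.ModelSpec(process=CESSATION, cuts=(), terms=(), frailty="none")
    spec1 = frailty.ModelSpec(process=CESSATION, cuts=(), terms=("sex",), frailty="none")
    ll0 = frailty.piecewise_exponential_loglik(rows, spec0, [-3.0])
    ll1 = frailty.piecewise_exponential_loglik(rows, spec1, [-3.0, 0.0])
    assert ll1 == pytest.approx(ll0, abs=1e-12)


def test_loglik_matches_term_by_term_rederivation():
    # 10-row fixture, frozen by summing d*(log lam + x b + u) - e lam e^(xb+u)
    rng = np.random.default_rng(8)
    rows = []
    for i in range(10):
        rows.append(make_row(
            person_id="p1", t0=0.0, t1=float(rng.integers(1, 60)),
            event=int(rng.random() < 0.4),
            baseline_interval=int(rng.integers(0, 2)),
            sex="female" if i % 2 else "male",
        ))
    df = rows_frame(rows)
    spec = frailty.ModelSpec(process=CESSATION, cuts=(30.0,), terms=("sex",),
                             frailty="none")
    theta = np.array([-3.2, -4.1, 0.7])
    u = 0.3
    expected = 0.0
    for r in rows:
        lam = math.exp(theta[r["baseline_interval"]])
        xb = theta[2] * (r["sex"] == "female")
        expected += r["event"] * (math.log(lam) + xb + u)
        expected -= r["exposure"] * lam * math.exp(xb + u)
    got = frailty.piecewise_exponential_loglik(df, spec, theta, u=u)
    assert got == pytest.approx(expected, abs=1e-10)


def test_marginal_at_zero_variance_equals_conditional():
    _, rows = cohort_rows(15, seed=100)
    spec = frailty.ModelSpec(process=CESSATION)
    prep = frailty._prepare(rows, spec)
    theta = frailty._initial_theta(prep, spec)
    cond = frailty.piecewise_exponential_loglik(rows, spec, theta, u=0.0)
    assert frailty.marginal_loglik(rows, spec, theta, 0.0) == pytest.approx(cond, abs=1e-9)


def test_quadrature_order_convergence():
    _, rows = cohort_rows(15, seed=100)
    spec = frailty.ModelSpec(process=CESSATION)
    prep = frailty._prepare(rows, spec)
    theta = frailty._initial_theta(prep, spec)
    l20 = frailty.marginal_loglik(rows, spec, theta, 1.0, quad_order=20)
    l50 = frailty.marginal_loglik(rows, spec, theta, 1.0, quad_order=50)
    assert abs(l20 - l50) < 1e-8


def test_occurrence_exposure_closed_form():
    # single interval, no covariates, no frailty: lam-hat = events/exposure
    _, rows = cohort_rows(25, seed=4)
    rows = _reindex_baseline(rows, ())
    res = frailty.fit(rows, FLAT, se=False)
    lam_hat = math.exp(res.coef[0])
    assert lam_hat == pytest.approx(rows["event"].sum() / rows["exposure"].sum(),
                                    rel=1e-6)


def test_optimizer_improves_on_initial_values(small_cohort_rows):
    res = frailty.fit(small_cohort_rows[CESSATION],
                      frailty.ModelSpec(process=CESSATION), se=False)
    assert res.loglik >= res.loglik_init
    assert res.converged


def test_lr_test_basics():
    assert frailty.lr_test(-100.0, -100.0, df=2) == 1.0
    p = frailty.lr_test(-100.0, -100.0 - 5.99 / 2, df=2)
    assert p == pytest.approx(chi2.sf(5.99, 2), abs=1e-12)
    assert p == pytest.approx(0.05, abs=1e-3)
    with pytest.raises(ValueError, match="non-nested"):
        frailty.lr_test(-101.0, -100.0, df=1)


def test_lr_boundary_mixture_halves_pvalue():
    dev = 3.2
    plain = frailty.lr_test(-100.0, -100.0 - dev / 2, df=1)
    mixed = frailty.lr_test(-100.0, -100.0 - dev / 2, df=1, boundary=True)
    assert mixed == pytest.approx(0.5 * plain, abs=1e-12)


# ---------------------------------------------------------------------------
# change-point selection

def _refitter(rows, terms=(), frailty_structure="none"):
    def fit_for_cuts(cuts):
        spec = frailty.ModelSpec(process=CESSATION, cuts=cuts, terms=terms,
                                 frailty=frailty_structure)
        return frailty.fit(rows, spec, se=False)
    return fit_for_cuts


def _reindex_baseline(rows, cuts):
    from cessrel.bands import baseline_interval_index
    rows = rows.copy()
    rows["baseline_interval"] = [baseline_interval_index(t, cuts)
                                 for t in rows["t0"]]
    return rows


def test_empty_candidate_set_returns_single_interval():
    _, rows = cohort_rows(10, seed=5)
    chosen, trail = frailty.select_changepoints(_refitter(rows), [])
    assert chosen == ()
    assert trail.empty


def test_constant_hazard_drops_extra_cuts_near_alpha():
    # type-I error of forward selection ~ alpha under a constant hazard
    params = cr.CareerParams(
        cessation_cuts=(), cessation_rates=(0.01,),
        relapse_cuts=(), relapse_rates=(0.004,),
        beta_cessation={}, beta_relapse={}, sigma2_cess=0.0, sigma2_rel=0.0,
    )
    kept = 0
    n_rep = 60
    for rep in range(n_rep):
        cohort = simulate.simulate_cohort(40, params, seed=9000 + rep)
        eps_by = {c.person_id: c.episodes for c in cohort}
        profs = {c.person_id: eb.profile_from_career(c) for c in cohort}
        rows = eb.build_cohort_records(eps_by, profs, CESSATION,
                                       decompose_ost=False)

        def fit_for_cuts(cuts):
            r = _reindex_baseline(rows, cuts)
            spec = frailty.ModelSpec(process=CESSATION, cuts=cuts, terms=(),
                                     frailty="none")
            return frailty.fit(r, spec, se=False)

        chosen, _ = frailty.select_changepoints(fit_for_cuts, [(), (60.0,)],
                                                alpha=0.05)
        kept += bool(chosen)
    # Binomial(60, 0.05): 3 expected; [0, 9] covers > 99.9%
    assert kept <= 9


def test_structured_baseline_retains_all_paper_cuts():
    # hazards with strong interval ratios: every cut is kept at n=405
    cohort, rows = cohort_rows(405, seed=77)
    nested = [(), (3.0,), (3.0, 7.0), (3.0, 7.0, 84.0), (3.0, 7.0, 84.0, 365.0)]

    def fit_for_cuts(cuts):
        r = _reindex_baseline(rows, cuts)
        spec = frailty.ModelSpec(process=CESSATION, cuts=cuts, terms=(),
                                 frailty="none")
        return frailty.fit(r, spec, se=False)

    chosen, trail = frailty.select_changepoints(fit_for_cuts, nested)
    assert chosen == (3.0, 7.0, 84.0, 365.0)
    assert trail["kept"].all()


# ---------------------------------------------------------------------------
# parameter recovery (smoke scale; the full study runs in the acceptance suite)

def test_null_covariates_estimated_near_zero():
    params = cr.CareerParams(beta_cessation={}, beta_relapse={},
                             sigma2_cess=0.3, sigma2_rel=0.3)
    _, rows = cohort_rows(300, seed=12, params=params)
    spec = frailty.ModelSpec(process=CESSATION,
                             terms=("sex", "onset_age", "onset_era"))
    res = frailty.fit(rows, spec)
    for nm in ("female", "onset_20plus", "onset_post1986"):
        coef = res.coef_named()[nm]
        se = res.se_named()[nm]
        assert abs(coef) < 4 * se


def test_bias_decreases_with_sample_size():
    truth = math.log(1.71)
    errs = {}
    for n in (200, 800):
        e = []
        for rep in range(4):
            _, rows = cohort_rows(n, seed=5000 + 13 * rep)
            res = frailty.fit(rows, frailty.ModelSpec(process=CESSATION), se=False)
            e.append(res.coef_named()["ost_on_within"] - truth)
        errs[n] = abs(np.mean(e))
    assert errs[800] < errs[200] + 0.05  # tolerate MC noise at 4 replicates


# ---------------------------------------------------------------------------
# joint model

def test_joint_rho_zero_factorizes(small_cohort_rows):
    rows_c = small_cohort_rows[CESSATION]
    rows_r = small_cohort_rows[RELAPSE]
    spec_c = frailty.ModelSpec(process=CESSATION, quad_order=15)
    spec_r = frailty.ModelSpec(process=RELAPSE, quad_order=15)
    fc = frailty.fit(rows_c, spec_c, se=False)
    fr = frailty.fit(rows_r, spec_r, se=False)
    jl = frailty.joint_marginal_loglik(
        rows_c, rows_r, spec_c, spec_r, fc.coef, fr.coef,
        fc.sigma2, fr.sigma2, rho=0.0, quad_order=15,
    )
    assert abs(jl - (fc.loglik + fr.loglik)) < 1e-8


def test_joint_null_rho_ci_covers_zero():
    params = cr.CareerParams(rho=0.0)
    cohort = simulate.simulate_cohort(150, params, seed=31)
    eps_by = {c.person_id: c.episodes for c in cohort}
    profs = {c.person_id: eb.profile_from_career(c) for c in cohort}
    rows_c = eb.build_cohort_records(eps_by, profs, CESSATION)
    rows_r = eb.build_cohort_records(eps_by, profs, RELAPSE)
    res = frailty.fit_joint(rows_c, rows_r,
                            frailty.ModelSpec(process=CESSATION),
                            frailty.ModelSpec(process=RELAPSE), quad_order=9)
    lo, hi = res.rho_ci()
    assert lo < 0.0 < hi
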
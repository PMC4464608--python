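# cessrel — recurrent cessation and relapse over the injecting career

People who inject drugs typically switch repeatedly between periods of
injecting and abstinence. Quantifying what drives each *cessation* (the
start of a ≥3-month non-injection period) and each *relapse* (its end)
over the whole injecting career requires three non-standard pieces of
statistical machinery, which this package implements and tests
end-to-end on synthetic cohorts:

1. **Life-grid imputation.** Retrospective questionnaires record, per
   calendar year, only whether a person injected, how many distinct
   ≥3-month non-injection periods occurred, and days spent injecting.
   A deterministic algorithm converts these annual counts into
   continuous-time episodes while *minimizing* the number of
   transitions: single periods are placed at the end of a year when the
   previous year finished injecting (otherwise at the beginning), two
   or three periods occupy beginning/middle/end, each year's
   non-injecting days are split equally among its periods, and periods
   flush to the two sides of a year boundary merge into one episode.

2. **Gap-time risk sets.** Episodes are expanded into counting-process
   rows in gap time (time since the current episode began), split so
   the baseline-hazard interval, OST status, current-age band and
   previous-event band are constant within each row.

3. **Piecewise-exponential frailty models.** The hazard for person *i*
   in episode *j* is

   h_ij(t) = h₀(t) · exp[ β_on OST_on,ij(t) + β_na OST_na,ij(t) + β_Z Z_ij(t) + u_i ]

   with h₀ piecewise-constant (cessation: ≤3 d, (3,7] d, (1,12] wk,
   (3,12] mo, >1 y; relapse: ≤2 mo, (2,12] mo, (1,2] y, >2 y) and
   u_i ~ N(0, σ²) a person-level random effect. To guard against
   confounding by cluster, each OST effect splits into a
   between-individual term on the follow-up fraction ŌST_i and a
   within-individual term on OST_ij(t) − ŌST_i. The marginal likelihood
   is maximized with adaptive Gauss–Hermite quadrature; a joint model
   links the two processes through correlated bivariate-normal
   frailties (u_cess, u_rel) with correlation ρ.

A synthetic-career generator (alternating renewal process with these
exact ingredients, a two-state masked OST process, and annual
coarsening that suppresses sub-3-month abstinences) stands in for the
cohort data, so the whole pipeline is reproducible from a seed.

## Worked example

```bash
python analysis/01_simulate_cohort.py     # 405 careers -> results/cohort/
python analysis/02_impute_episodes.py
python analysis/03_kaplan_meier.py
python analysis/04_fit_hazard_models.py
python analysis/05_joint_frailty_model.py
```

The drivers print, for the default seed (20150601) — abridged:

```
median transitions 3 (IQR 1-7); 5.4% made none; 66.4% relapsed at least once
imputed/true transition totals: 2348/3480 (imputation minimizes transitions)
cessation: n=405, events=383; P(event<=12mo)=0.50, P(event<=5y)=0.78; median 1.0 y, IQR (0.16, 3.94)
relapse: n=383, events=269; P(event<=12mo)=0.32, P(event<=5y)=0.55; median 3.41 y, IQR (0.81, 26.17)
== cessation ==  within-OST HR 1.47 (2-df LR p=1.2e-05), sigma^2 = 0.79 (0.56-1.11)
== relapse ==    within-OST HR 0.80 (2-df LR p=0.016),  sigma^2 = 0.31 (0.13-0.73)
```

Reading: within an individual, time on opiate substitution treatment
raises the cessation hazard by roughly half (HR > 1 means a higher
hazard, hence shorter injecting episodes), while the relapse hazard is
modestly reduced; the between-individual OST terms go the opposite way,
the signature of confounding by cluster. The imputed hazards sit below
the generative truth because the annual grid cannot see short
abstinences and the imputation deliberately minimizes transitions —
both visible in the imputed/true transition totals.

The same pipeline is scriptable via the `cessrel` CLI
(`simulate | impute | expand | km | fit | report | all`), e.g.
`cessrel all --n 100 --seed 7 --outdir results/demo`.

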
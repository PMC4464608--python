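"""Pipeline orchestration and cohort summaries.

Chains simulate -> impute -> expand -> km/fit on one configuration,
writes every stage's table under an output directory, and records a run
manifest (package versions, seed, config hash, imputation warning
counts, output checksums) so that identical configurations are
verifiably reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from cessrel import episodes as episode_builder
from cessrel import frailty, lifegrid, simulate, survival
from cessrel.bands import CESSATION, RELAPSE, YEAR
from cessrel.episodes import CovariateProfile
from cessrel.lifegrid import ImputationWarnings
from cessrel.params import CareerParams

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "impute", "expand", "km", "fit", "report")


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    mode: str = "simulate"                   # "simulate" | "real"
    n: int = 405
    seed: int = 20150601
    params: CareerParams = field(default_factory=CareerParams)
    stages: tuple[str, ...] = ALL_STAGES
    # real-data inputs (ignored in simulate mode)
    lifegrid_csv: str | None = None
    covariates_csv: str | None = None
    ost_csv: str | None = None
    # modelling options
    terms: tuple[str, ...] = frailty.DEFAULT_TERMS
    frailty_structure: str = "normal"
    quad_order: int = 20
    joint: bool = False
    joint_quad_order: int = 9

    def validate(self) -> None:
        if self.mode not in ("simulate", "real"):
            raise ValueError(f"unknown mode {self.mode!r}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.mode == "simulate":
            if self.seed is None:
                raise ValueError("simulation mode requires a seed")
            self.params.validate()
        else:
            for p in (self.lifegrid_csv, self.covariates_csv, self.ost_csv):
                if p is None or not Path(p).exists():
                    raise ValueError(f"real-data mode requires existing input file, got {p}")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["params"] = self.params.to_dict()
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "params" in d:
            d["params"] = CareerParams.from_dict(d["params"])
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def profiles_from_tables(cov: pd.DataFrame, ost: pd.DataFrame) -> dict[str, CovariateProfile]:
    """Build per-person covariate profiles from the covariates/OST tables."""
    ost_by_pid: dict[str, list[tuple[float, float, str]]] = {}
    for r in ost.itertuples():
        ost_by_pid.setdefault(str(r.person_id), []).append(
            (float(r.start_day), float(r.end_day), str(r.status))
        )
    profiles = {}
    for r in cov.itertuples():
        pid = str(r.person_id)
        onset_age = int(r.onset_year) - int(r.birth_year)
        profiles[pid] = CovariateProfile(
            person_id=pid,
            sex=str(r.sex),
            onset_year=int(r.onset_year),
            birth_day=-onset_age * YEAR,
            censor_day=float(r.censor_day),
            ost_intervals=sorted(ost_by_pid.get(pid, [])),
        )
    return profiles


def transition_summary(
    episodes_by_person: dict[str, list[lifegrid.Episode]],
    followup_years: dict[str, float],
) -> dict[str, Any]:
    """Cohort summary of per-person transition (cessation+relapse) counts."""
    if not episodes_by_person:
        raise ValueError("empty cohort")
    counts, rates = [], []
    n_zero = n_short_no_relapse = n_any_relapse = 0
    for pid, eps in episodes_by_person.items():
        nc, nr = lifegrid.count_transitions(eps)
        total = nc + nr
        counts.append(total)
        fy = followup_years[pid]
        rates.append(total / fy if fy > 0 else math.nan)
        if total == 0:
            n_zero += 1
        if nr >= 1:
            n_any_relapse += 1
        first_inj = next(ep for ep in sorted(eps, key=lambda e: e.start_day)
                         if ep.kind == lifegrid.INJECTING)
        if (first_inj.terminal == lifegrid.CESSATION_EVENT
                and first_inj.length < YEAR and nr == 0):
            n_short_no_relapse += 1
    counts_arr = np.array(counts)
    n = len(counts)
    return {
        "n_persons": n,
        "median_transitions": float(np.median(counts_arr)),
        "iqr_transitions": [float(np.percentile(counts_arr, 25)),
                            float(np.percentile(counts_arr, 75))],
        "mean_transitions": float(counts_arr.mean()),
        "sd_transitions": float(counts_arr.std(ddof=1)) if n > 1 else 0.0,
        "max_transitions": int(counts_arr.max()),
        "pct_zero_transitions": 100.0 * n_zero / n,
        "pct_short_injector_no_relapse": 100.0 * n_short_no_relapse / n,
        "pct_at_least_one_relapse": 100.0 * n_any_relapse / n,
        "mean_rate_per_year": float(np.nanmean(rates)),
        "median_rate_per_year": float(np.nanmedian(rates)),
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages; return the in-memory report bundle."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {}
    warn = ImputationWarnings()
    stage = "setup"
    try:
        # ------------------------------------------------ inputs
        if config.mode == "simulate":
            if "simulate" in config.stages:
                stage = "simulate"
                careers = simulate.simulate_cohort(config.n, config.params, config.seed)
                tables = simulate.careers_to_tables(careers, config.params)
                for name, df in tables.items():
                    df.to_csv(out / f"{name}.csv", index=False)
                bundle["tables"] = tables
            else:
                tables = {name: pd.read_csv(out / f"{name}.csv")
                          for name in ("lifegrid", "covariates", "ost")}
        else:
            tables = {
                "lifegrid": pd.read_csv(config.lifegrid_csv),
                "covariates": pd.read_csv(config.covariates_csv),
                "ost": pd.read_csv(config.ost_csv),
            }
            bundle["tables"] = tables

        profiles = profiles_from_tables(tables["covariates"], tables["ost"])
        interview_days = {pid: prof.censor_day for pid, prof in profiles.items()}

        # ------------------------------------------------ impute
        stage = "impute"
        grids = lifegrid.grids_from_frame(tables["lifegrid"], interview_days)
        episodes_by_person = {
            g.person_id: lifegrid.impute_event_times(g, warnings=warn) for g in grids
        }
        if "impute" in config.stages:
            ep_df = lifegrid.episodes_to_frame(
                [ep for eps in episodes_by_person.values() for ep in eps]
            )
            ep_df.to_csv(out / "episodes.csv", index=False)
            bundle["episodes"] = episodes_by_person

        # ------------------------------------------------ expand
        rows = {}
        if {"expand", "fit"} & set(config.stages):
            stage = "expand"
            for process in (CESSATION, RELAPSE):
                rows[process] = episode_builder.build_cohort_records(
                    episodes_by_person, profiles, process,
                    include_decade=("decade" in config.terms),
                )
                rows[process].to_csv(out / f"riskset_{process}.csv", index=False)
            bundle["riskset"] = rows

        # ------------------------------------------------ km
        if "km" in config.stages:
            stage = "km"
            bundle["km"] = {}
            for process in (CESSATION, RELAPSE):
                t, d = survival.first_event_dataset(episodes_by_person, process)
                curve = survival.kaplan_meier(t, d)
                survival.write_km_outputs(
                    curve, str(out / f"km_{process}.csv"), str(out / f"km_{process}.json")
                )
                bundle["km"][process] = curve

        # ------------------------------------------------ fit
        if "fit" in config.stages:
            stage = "fit"
            bundle["fits"] = {}
            for process in (CESSATION, RELAPSE):
                spec = frailty.ModelSpec(
                    process=process, terms=config.terms,
                    frailty=config.frailty_structure, quad_order=config.quad_order,
                )
                res = frailty.fit(rows[process], spec)
                bundle["fits"][process] = res
                write_fit_outputs(res, out / f"fit_{process}.csv",
                                  out / f"fit_{process}.json", seed=config.seed)
            if config.joint:
                spec_c = frailty.ModelSpec(process=CESSATION, terms=config.terms)
                spec_r = frailty.ModelSpec(process=RELAPSE, terms=config.terms)
                res = frailty.fit_joint(rows[CESSATION], rows[RELAPSE], spec_c, spec_r,
                                        quad_order=config.joint_quad_order)
                bundle["fits"]["joint"] = res
                write_fit_outputs(res, out / "fit_joint.csv", out / "fit_joint.json",
                                  seed=config.seed)

        # ------------------------------------------------ report
        if "report" in config.stages:
            stage = "report"
            followup_years = {pid: prof.censor_day / YEAR for pid, prof in profiles.items()}
            summ = transition_summary(episodes_by_person, followup_years)
            with open(out / "transition_summary.json", "w") as fh:
                json.dump(summ, fh, indent=2)
            bundle["transition_summary"] = summ
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "versions": _versions(),
        "imputation_warnings": warn.as_dict(),
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.glob("*.csv")) if p.is_file()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    bundle["manifest"] = manifest
    return bundle


def _versions() -> dict[str, str]:
    import scipy
    import statsmodels

    import cessrel

    return {
        "cessrel": cessrel.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }


def write_fit_outputs(res: frailty.FitResult, csv_path, json_path, seed=None) -> None:
    """Results table (term, HR, CI, p) plus variance rows, and a JSON record."""
    tab = res.summary()
    extra = []
    if res.sigma2 is not None:
        ci = res.sigma2_ci()
        extra.append({
            "term": "sigma2" if res.rho is None else "sigma2_cessation",
            "coef": math.log(res.sigma2), "se": res.sigma2_se_log,
            "hr": res.sigma2,
            "hr_low": ci[0] if ci else np.nan, "hr_high": ci[1] if ci else np.nan,
            "p_wald": np.nan,
        })
    if res.sigma2_rel is not None:
        ci = _sigma2_rel_ci(res)
        extra.append({
            "term": "sigma2_relapse", "coef": math.log(res.sigma2_rel),
            "se": res.sigma2_rel_se_log, "hr": res.sigma2_rel,
            "hr_low": ci[0] if ci else np.nan, "hr_high": ci[1] if ci else np.nan,
            "p_wald": np.nan,
        })
    if res.rho is not None:
        ci = res.rho_ci()
        extra.append({
            "term": "rho", "coef": res.rho, "se": res.rho_se_z, "hr": np.nan,
            "hr_low": ci[0] if ci else np.nan, "hr_high": ci[1] if ci else np.nan,
            "p_wald": np.nan,
        })
    if extra:
        tab = pd.concat([tab, pd.DataFrame(extra)], ignore_index=True)
    tab.to_csv(csv_path, index=False)
    record = {
        "loglik": res.loglik,
        "converged": res.converged,
        "grad_norm": res.grad_norm,
        "n_persons": res.n_persons,
        "n_rows": res.n_rows,
        "seed": seed,
        "spec": {
            "process": res.spec.process,
            "cuts": list(res.spec.resolved_cuts()),
            "terms": list(res.spec.terms),
            "frailty": res.spec.frailty,
            "quad_order": res.spec.quad_order,
        },
        "sigma2": res.sigma2,
        "sigma2_relapse": res.sigma2_rel,
        "rho": res.rho,
    }
    with open(json_path, "w") as fh:
        json.dump(record, fh, indent=2)


def _sigma2_rel_ci(res: frailty.FitResult, alpha: float = 0.05):
    if res.sigma2_rel is None or res.sigma2_rel_se_log is None:
        return None
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    ls = math.log(max(res.sigma2_rel, 1e-300))
    return (math.exp(ls - z * res.sigma2_rel_se_log),
            math.exp(ls + z * res.sigma2_rel_se_log))
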
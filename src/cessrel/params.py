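"""Simulation truth: hazards, covariate effects, frailty and OST process.

`CareerParams` holds everything needed to generate a synthetic injecting
career as an alternating renewal process: piecewise-constant baseline
hazards for cessation (while injecting) and relapse (while not
injecting), named log-hazard-ratio maps for the covariates, normal
random-effect (frailty) variances on the log-hazard scale with optional
correlation, a two-state opiate-substitution-treatment (OST) process
with masking, and the cohort-design quantities (onset age/year
distributions, sex mix, interview window).

Default values describe a cohort of 405 people who inject drugs
followed from first injection (1970s-1990s onset) to interview in
2005-2007, with covariate hazard ratios and frailty variances at
realistic magnitudes for that population; baseline rate levels are set
so that the marginal time to first cessation has a median of roughly
1.5 years and the time from first cessation to relapse a median of
roughly 2.4 years.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

from cessrel import bands

_CESS_BASE = 0.024  # events/day in the <=3 day reference interval
_REL_BASE = 0.00145  # events/day in the <=2 month reference interval


def _default_cessation_rates() -> tuple[float, ...]:
    return tuple(_CESS_BASE * r for r in (1.0, 0.51, 0.09, 0.04, 0.03))


def _default_relapse_rates() -> tuple[float, ...]:
    return tuple(_REL_BASE * r for r in (1.0, 0.87, 0.38, 0.10))


def _default_beta_cessation() -> dict[str, float]:
    return {
        "female": math.log(1.05),
        "onset_20plus": math.log(1.32),
        "onset_post1986": math.log(1.37),
        "age_lt20": math.log(0.94),
        "age_26_30": math.log(0.96),
        "age_31_35": math.log(1.10),
        "age_36plus": math.log(1.15),
        "ost_on": math.log(1.71),
        "ost_unknown": math.log(1.11),
        "prev_1_2": math.log(1.19),
        "prev_3_4": math.log(1.52),
        "prev_5_9": math.log(2.67),
        "prev_10plus": math.log(3.58),
    }


def _default_beta_relapse() -> dict[str, float]:
    return {
        "female": math.log(0.73),
        "onset_20plus": math.log(1.40),
        "onset_post1986": math.log(1.22),
        "age_lt20": math.log(1.06),
        "age_26_30": math.log(0.70),
        "age_31_35": math.log(0.77),
        "age_36plus": math.log(0.55),
        "ost_on": math.log(0.81),
        "ost_unknown": math.log(0.83),
        "prev_1_2": math.log(1.27),
        "prev_3_4": math.log(1.36),
        "prev_5_9": math.log(1.44),
        "prev_10plus": math.log(1.54),
    }


#: covariate keys understood by the generator's linear predictor
KNOWN_BETA_KEYS = frozenset(_default_beta_cessation())


@dataclass
class CareerParams:
    """Ground-truth parameters for synthetic injecting careers."""

    # piecewise-constant baseline hazards (events/day) and their gap-time
    # cut points (days); rates has one more entry than cuts
    cessation_cuts: tuple[float, ...] = bands.CESSATION_CUTS
    cessation_rates: tuple[float, ...] = field(default_factory=_default_cessation_rates)
    relapse_cuts: tuple[float, ...] = bands.RELAPSE_CUTS
    relapse_rates: tuple[float, ...] = field(default_factory=_default_relapse_rates)

    # named log hazard ratios
    beta_cessation: dict[str, float] = field(default_factory=_default_beta_cessation)
    beta_relapse: dict[str, float] = field(default_factory=_default_beta_relapse)

    # frailty: var of the person-specific log-hazard offsets and their
    # correlation between the cessation and relapse processes
    sigma2_cess: float = 0.90
    sigma2_rel: float = 0.57
    rho: float = 0.0

    # OST process: continuous-time two-state chain (off <-> on) plus an
    # independent per-sojourn masking probability producing "unknown"
    ost_on_rate: float = 1.0 / 1095.0   # off -> on, per day
    ost_off_rate: float = 1.0 / 365.0   # on -> off, per day
    ost_unknown_prob: float = 0.20

    # cohort design
    onset_age_range: tuple[float, float] = (14.0, 30.0)
    onset_year_range: tuple[int, int] = (1970, 2001)
    sex_probability: float = 0.30       # P(female)
    interview_years: tuple[int, int] = (2005, 2007)

    # life-grid elicitation floor: abstinences shorter than this are not
    # reported (3 months)
    min_period_days: float = 90.0

    def validate(self) -> None:
        for name, cuts, rates in (
            ("cessation", self.cessation_cuts, self.cessation_rates),
            ("relapse", self.relapse_cuts, self.relapse_rates),
        ):
            if len(rates) != len(cuts) + 1:
                raise ValueError(
                    f"{name}: need len(rates) == len(cuts)+1, "
                    f"got {len(rates)} rates for {len(cuts)} cuts"
                )
            if any(r <= 0 or not math.isfinite(r) for r in rates):
                raise ValueError(f"{name}: hazard rates must be positive and finite")
            if list(cuts) != sorted(cuts) or len(set(cuts)) != len(cuts):
                raise ValueError(f"{name}: cut points must be strictly increasing")
            if cuts and cuts[0] <= 0:
                raise ValueError(f"{name}: cut points must be positive")
        for beta in (self.beta_cessation, self.beta_relapse):
            unknown = set(beta) - KNOWN_BETA_KEYS
            if unknown:
                raise ValueError(f"unknown covariate keys: {sorted(unknown)}")
        if self.sigma2_cess < 0 or self.sigma2_rel < 0:
            raise ValueError("frailty variances must be non-negative")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("frailty correlation must lie in [-1, 1]")
        if self.ost_on_rate <= 0 or self.ost_off_rate <= 0:
            raise ValueError("OST transition rates must be positive")
        if not 0.0 <= self.ost_unknown_prob <= 1.0:
            raise ValueError("OST masking probability must lie in [0, 1]")
        if not 0.0 <= self.sex_probability <= 1.0:
            raise ValueError("sex probability must lie in [0, 1]")
        if self.onset_age_range[0] > self.onset_age_range[1]:
            raise ValueError("onset age range reversed")
        if self.onset_year_range[0] > self.onset_year_range[1]:
            raise ValueError("onset year range reversed")
        if self.interview_years[0] > self.interview_years[1]:
            raise ValueError("interview year range reversed")
        if self.onset_year_range[1] >= self.interview_years[0]:
            raise ValueError("onset years must precede the interview window")
        if self.min_period_days < 0:
            raise ValueError("elicitation floor must be non-negative")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CareerParams":
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
        p = cls(**kwargs)
        p.validate()
        return p

    @classmethod
    def from_yaml(cls, path: str) -> "CareerParams":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
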
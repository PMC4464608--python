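"""Piecewise-exponential proportional-hazards models with normal frailty.

The hazard for person i in episode j at gap time t is

    h_ij(t) = h0(t) * exp(x_ij(t)' beta + u_i)

with h0 piecewise-constant over configurable gap-time intervals and
u_i ~ N(0, sigma^2) a person-level random effect on the log-hazard
scale.  On counting-process rows (constant hazard within a row) the
conditional log-likelihood is the familiar occurrence/exposure form

    sum_rows [ d * (log lambda + x'beta + u) - e * lambda * exp(x'beta + u) ]

and the marginal likelihood integrates the person-level factor over u
by *adaptive* Gauss-Hermite quadrature: nodes are recentred at the
person's conditional mode and rescaled by the local curvature, which
keeps a modest node count accurate even for informative persons.

`fit` maximizes the marginal likelihood over (baseline log-rates, beta,
log sigma^2) by quasi-Newton with analytic score (Fisher's identity:
the score is the posterior expectation of the conditional score).
`fit_joint` extends this to a bivariate normal frailty pair linking the
cessation and relapse processes, with correlation rho estimated on the
atanh scale and 2-D adaptive Gauss-Hermite quadrature.

Standard errors come from the numerically differentiated observed
information; Wald intervals are formed on the estimation scale and
transformed (hazard-ratio scale for beta, exponential for sigma^2,
tanh for rho).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.stats import chi2, norm

from cessrel import bands
from cessrel.bands import CESSATION, RELAPSE

logger = logging.getLogger(__name__)


def _hess_from_grad(x: np.ndarray, grad_fun, rel_step: float = 1e-5) -> np.ndarray:
    """Observed information by central differences of the analytic score."""
    k = x.size
    H = np.empty((k, k))
    for i in range(k):
        h = rel_step * (1.0 + abs(x[i]))
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        H[i] = (grad_fun(xp) - grad_fun(xm)) / (2.0 * h)
    return 0.5 * (H + H.T)

_SQRT2 = math.sqrt(2.0)
_LOG2PI = math.log(2.0 * math.pi)

#: covariate term blocks -> design columns
KNOWN_TERMS = (
    "sex", "onset_age", "onset_era", "current_age",
    "ost", "ost_decomposed", "prev_events", "decade",
)

DEFAULT_TERMS = ("sex", "onset_age", "onset_era", "current_age",
                 "ost_decomposed", "prev_events")


@dataclass(frozen=True)
class ModelSpec:
    """Definition of one piecewise-exponential frailty model."""

    process: str = CESSATION                  # cessation / relapse / joint
    cuts: tuple[float, ...] | None = None     # None -> field defaults
    terms: tuple[str, ...] = DEFAULT_TERMS
    frailty: str = "normal"                   # "none" | "normal"
    quad_order: int = 20
    gtol: float = 1e-6
    maxiter: int = 1000

    def resolved_cuts(self) -> tuple[float, ...]:
        if self.cuts is not None:
            return tuple(self.cuts)
        return bands.default_cuts(self.process)

    def validate(self) -> None:
        cuts = self.resolved_cuts()
        if list(cuts) != sorted(set(cuts)):
            raise ValueError("cut points must be strictly increasing")
        unknown = {t for t in self.terms
                   if t not in KNOWN_TERMS and not t.startswith("col:")}
        if unknown:
            raise ValueError(f"unknown model terms: {sorted(unknown)}")
        if "ost" in self.terms and "ost_decomposed" in self.terms:
            raise ValueError("use either 'ost' or 'ost_decomposed', not both")
        if self.frailty not in ("none", "normal"):
            raise ValueError(f"unknown frailty structure {self.frailty!r}")
        if self.quad_order < 2:
            raise ValueError("quadrature order must be >= 2")


@dataclass
class FitResult:
    """Maximum-likelihood estimates with Wald uncertainty."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_init: float
    n_persons: int
    n_rows: int
    converged: bool
    grad_norm: float
    spec: ModelSpec
    sigma2: float | None = None
    sigma2_se_log: float | None = None      # SE of log sigma^2
    sigma2_rel: float | None = None         # joint model only
    sigma2_rel_se_log: float | None = None
    rho: float | None = None
    rho_se_z: float | None = None           # SE of atanh(rho)
    singular_information: bool = False
    message: str = ""

    @property
    def n_baseline(self) -> int:
        return len(self.spec.resolved_cuts()) + 1

    def ci(self, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        z = norm.ppf(1 - alpha / 2)
        return self.coef - z * self.se, self.coef + z * self.se

    def sigma2_ci(self, alpha: float = 0.05) -> tuple[float, float] | None:
        if self.sigma2 is None or self.sigma2_se_log is None:
            return None
        z = norm.ppf(1 - alpha / 2)
        ls = math.log(max(self.sigma2, 1e-300))
        return (math.exp(ls - z * self.sigma2_se_log),
                math.exp(ls + z * self.sigma2_se_log))

    def rho_ci(self, alpha: float = 0.05) -> tuple[float, float] | None:
        if self.rho is None or self.rho_se_z is None:
            return None
        z = norm.ppf(1 - alpha / 2)
        zz = math.atanh(max(min(self.rho, 1 - 1e-12), -1 + 1e-12))
        return (math.tanh(zz - z * self.rho_se_z), math.tanh(zz + z * self.rho_se_z))

    def coef_named(self) -> dict[str, float]:
        return dict(zip(self.names, self.coef))

    def se_named(self) -> dict[str, float]:
        return dict(zip(self.names, self.se))

    def summary(self) -> pd.DataFrame:
        lo, hi = self.ci()
        z = np.full_like(self.coef, np.nan)
        ok = self.se > 0
        z[ok] = self.coef[ok] / self.se[ok]
        p = 2 * norm.sf(np.abs(z))
        with np.errstate(over="ignore"):  # a CI bound may overflow to inf
            return pd.DataFrame({
                "term": self.names,
                "coef": self.coef,
                "se": self.se,
                "hr": np.exp(self.coef),
                "hr_low": np.exp(lo),
                "hr_high": np.exp(hi),
                "p_wald": p,
            })


# ---------------------------------------------------------------------------
# design matrix

def build_design(rows: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Design matrix: baseline-interval dummies (no intercept) + covariates."""
    spec.validate()
    cuts = spec.resolved_cuts()
    labels = bands.baseline_interval_labels(cuts)
    cols: list[np.ndarray] = []
    names: list[str] = []
    base = rows["baseline_interval"].to_numpy()
    for i, lab in enumerate(labels):
        cols.append((base == i).astype(float))
        names.append(f"base[{lab}]")
    for term in spec.terms:
        if term == "sex":
            cols.append((rows["sex"] == "female").to_numpy(float))
            names.append("female")
        elif term == "onset_age":
            cols.append((rows["onset_age_band"] == "20+").to_numpy(float))
            names.append("onset_20plus")
        elif term == "onset_era":
            cols.append((rows["onset_era"] == ">=1986").to_numpy(float))
            names.append("onset_post1986")
        elif term == "current_age":
            for lab2, nm in (("<20", "age_lt20"), ("26-30", "age_26_30"),
                             ("31-35", "age_31_35"), ("35+", "age_36plus")):
                cols.append((rows["current_age_band"] == lab2).to_numpy(float))
                names.append(nm)
        elif term == "ost":
            cols.append((rows["ost_status"] == "on").to_numpy(float))
            names.append("ost_on")
            cols.append((rows["ost_status"] == "unknown").to_numpy(float))
            names.append("ost_unknown")
        elif term == "ost_decomposed":
            for c in ("ost_on_between", "ost_on_within", "ost_na_between", "ost_na_within"):
                if c not in rows.columns:
                    raise ValueError(
                        f"decomposed OST column {c!r} missing; run apply_within_between first"
                    )
                cols.append(rows[c].to_numpy(float))
                names.append(c)
        elif term == "prev_events":
            for lab2, nm in (("1-2", "prev_1_2"), ("3-4", "prev_3_4"),
                             ("5-9", "prev_5_9"), ("10+", "prev_10plus")):
                cols.append((rows["prev_event_band"] == lab2).to_numpy(float))
                names.append(nm)
        elif term == "decade":
            decades = sorted(d for d in rows["decade"].unique() if d)
            for dec in decades[1:]:   # earliest decade is the reference
                cols.append((rows["decade"] == dec).to_numpy(float))
                names.append(f"decade_{dec}")
        elif term.startswith("col:"):
            # raw numeric column, e.g. for constrained reparameterizations
            colname = term[4:]
            cols.append(rows[colname].to_numpy(float))
            names.append(colname)
    X = np.column_stack(cols) if cols else np.empty((len(rows), 0))
    return X, names


@dataclass
class _Prepared:
    X: np.ndarray
    names: list[str]
    d: np.ndarray
    e: np.ndarray
    pid: np.ndarray       # person codes 0..n-1
    persons: list[str]
    D: np.ndarray         # per-person event totals
    s: np.ndarray         # X' d

    @property
    def n(self) -> int:
        return len(self.persons)


def _prepare(rows: pd.DataFrame, spec: ModelSpec,
             persons: Sequence[str] | None = None) -> _Prepared:
    if len(rows) == 0:
        raise ValueError("no risk-set rows")
    keep = rows["exposure"].to_numpy() > 0
    if not keep.all():
        logger.warning("dropping %d zero-exposure rows", (~keep).sum())
        rows = rows.loc[keep]
    X, names = build_design(rows, spec)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in design matrix")
    d = rows["event"].to_numpy(float)
    e = rows["exposure"].to_numpy(float)
    if persons is None:
        persons = sorted(rows["person_id"].unique())
    index = {p: i for i, p in enumerate(persons)}
    pid = rows["person_id"].map(index).to_numpy(int)
    n = len(persons)
    D = np.bincount(pid, weights=d, minlength=n)
    s = X.T @ d
    return _Prepared(X, names, d, e, pid, list(persons), D, s)


# ---------------------------------------------------------------------------
# likelihood pieces

def piecewise_exponential_loglik(rows: pd.DataFrame, spec: ModelSpec,
                                 theta: np.ndarray, u: float = 0.0) -> float:
    """Conditional log-likelihood of rows given a common frailty value u."""
    X, _ = build_design(rows, spec)
    d = rows["event"].to_numpy(float)
    e = rows["exposure"].to_numpy(float)
    eta = X @ np.asarray(theta, float) + u
    val = float(d @ eta - e @ np.exp(eta))
    if not math.isfinite(val):
        bad = np.nonzero(~np.isfinite(d * eta - e * np.exp(eta)))[0]
        raise FloatingPointError(f"non-finite log-likelihood at rows {bad[:5]}")
    return val


def _mode_univariate(D: np.ndarray, B: np.ndarray, s2: float) -> tuple[np.ndarray, np.ndarray]:
    """Mode and curvature of u -> D u - B e^u - u^2/(2 s2), vectorized."""
    u = np.zeros_like(D)
    for _ in range(100):
        eu = np.exp(u)
        g1 = D - B * eu - u / s2
        g2 = -B * eu - 1.0 / s2
        step = np.clip(g1 / g2, -5.0, 5.0)
        u = u - step
        if np.max(np.abs(step)) < 1e-12:
            break
    eu = np.exp(u)
    g2 = -B * eu - 1.0 / s2
    return u, g2


def _agh_univariate(D: np.ndarray, B: np.ndarray, s2: float, order: int,
                    want_post: bool = False):
    """Per-person log integral of exp(D u - B e^u) against N(0, s2).

    Returns (L, E[e^u], E[u^2]) with the expectations under the
    posterior when ``want_post``.
    """
    z, w = hermgauss(order)
    logw = np.log(w)
    uhat, g2 = _mode_univariate(D, B, s2)
    tau = 1.0 / np.sqrt(-g2)
    U = uhat[:, None] + _SQRT2 * tau[:, None] * z[None, :]
    G = D[:, None] * U - B[:, None] * np.exp(U) - U * U / (2.0 * s2)
    A = logw[None, :] + (z * z)[None, :] + G
    amax = A.max(axis=1)
    expa = np.exp(A - amax[:, None])
    ssum = expa.sum(axis=1)
    L = math.log(_SQRT2) + np.log(tau) - 0.5 * math.log(2.0 * math.pi * s2) + amax + np.log(ssum)
    if not np.all(np.isfinite(L)):
        raise FloatingPointError(
            "non-finite quadrature value; try a higher order or rescaled data"
        )
    if not want_post:
        return L, None, None
    p = expa / ssum[:, None]
    Eeu = (p * np.exp(U)).sum(axis=1)
    Eu2 = (p * U * U).sum(axis=1)
    return L, Eeu, Eu2


def marginal_loglik(rows: pd.DataFrame, spec: ModelSpec, theta: np.ndarray,
                    sigma2: float, quad_order: int | None = None) -> float:
    """Marginal log-likelihood with the person frailties integrated out.

    Continuous in sigma^2: at sigma^2 = 0 the integral degenerates and
    the value equals the conditional log-likelihood at u = 0.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    prep = _prepare(rows, spec)
    theta = np.asarray(theta, float)
    order = quad_order if quad_order is not None else spec.quad_order
    eta = prep.X @ theta
    c = prep.e * np.exp(eta)
    T1 = float(prep.d @ eta)
    if sigma2 < 1e-12:
        return T1 - float(c.sum())
    B = np.bincount(prep.pid, weights=c, minlength=prep.n)
    L, _, _ = _agh_univariate(prep.D, B, sigma2, order)
    return T1 + float(L.sum())


def _nll_and_grad_univariate(params: np.ndarray, prep: _Prepared, order: int,
                             frailty: bool) -> tuple[float, np.ndarray]:
    p = prep.X.shape[1]
    theta = params[:p]
    eta = prep.X @ theta
    c = prep.e * np.exp(eta)
    T1 = float(prep.d @ eta)
    if not frailty:
        ll = T1 - float(c.sum())
        grad = prep.s - prep.X.T @ c
        return -ll, -grad
    s2 = math.exp(params[p])
    B = np.bincount(prep.pid, weights=c, minlength=prep.n)
    L, Eeu, Eu2 = _agh_univariate(prep.D, B, s2, order, want_post=True)
    ll = T1 + float(L.sum())
    grad_theta = prep.s - prep.X.T @ (c * Eeu[prep.pid])
    grad_ls2 = 0.5 * float(np.sum(Eu2 / s2 - 1.0))
    grad = np.concatenate([grad_theta, [grad_ls2]])
    return -ll, -grad


def _initial_theta(prep: _Prepared, spec: ModelSpec) -> np.ndarray:
    """Baseline log-rates from per-interval occurrence/exposure; beta = 0."""
    k = len(spec.resolved_cuts()) + 1
    theta = np.zeros(prep.X.shape[1])
    for i in range(k):
        mask = prep.X[:, i] == 1.0
        ev = prep.d[mask].sum()
        ex = prep.e[mask].sum()
        theta[i] = math.log((ev + 0.5) / (ex + 1.0))
    return theta


def fit(rows: pd.DataFrame, spec: ModelSpec,
        se: bool = True) -> FitResult:
    """Maximum-likelihood fit of one process's piecewise-exponential model."""
    spec.validate()
    prep = _prepare(rows, spec)
    frailty = spec.frailty == "normal"
    theta0 = _initial_theta(prep, spec)
    x0 = np.concatenate([theta0, [math.log(0.25)]]) if frailty else theta0

    fun = lambda x: _nll_and_grad_univariate(x, prep, spec.quad_order, frailty)
    ll_init = -fun(x0)[0]
    res = minimize(fun, x0, jac=True, method="BFGS",
                   options={"gtol": spec.gtol, "maxiter": spec.maxiter})
    xhat = res.x
    ll = -float(res.fun)
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success) or grad_norm < 1e-3
    if not converged:
        logger.warning("fit did not converge: %s (grad max %.3g)", res.message, grad_norm)

    p = prep.X.shape[1]
    se_all = np.full(xhat.size, np.nan)
    singular = False
    if se:
        h = _hess_from_grad(xhat, lambda x: fun(x)[1])
        try:
            cov = np.linalg.inv(h)
            diag = np.diag(cov)
            if np.any(diag <= 0):
                raise np.linalg.LinAlgError("non-positive variance")
            se_all = np.sqrt(diag)
        except np.linalg.LinAlgError:
            singular = True
            logger.warning("singular observed information; SEs omitted")

    return FitResult(
        names=prep.names,
        coef=xhat[:p],
        se=se_all[:p],
        loglik=ll,
        loglik_init=ll_init,
        n_persons=prep.n,
        n_rows=len(prep.d),
        converged=converged,
        grad_norm=grad_norm,
        spec=spec,
        sigma2=math.exp(xhat[p]) if frailty else None,
        sigma2_se_log=(se_all[p] if frailty else None),
        singular_information=singular,
        message=str(res.message),
    )


# ---------------------------------------------------------------------------
# likelihood-ratio machinery

def lr_test(full: FitResult | float, reduced: FitResult | float, df: int,
            boundary: bool = False) -> float:
    """P-value of the likelihood-ratio test of nested fits.

    ``boundary=True`` applies the 50:50 mixture chi2_{df-1}/chi2_{df}
    appropriate when one tested parameter (a variance) sits on the
    boundary of its space under the null.
    """
    ll_full = full.loglik if isinstance(full, FitResult) else float(full)
    ll_red = reduced.loglik if isinstance(reduced, FitResult) else float(reduced)
    dev = 2.0 * (ll_full - ll_red)
    if dev < -1e-6:
        raise ValueError(
            f"full model has lower log-likelihood (deviance {dev:.3g}); "
            "models are non-nested or the optimizer did not converge"
        )
    dev = max(dev, 0.0)
    if df < 1:
        raise ValueError("df must be >= 1")
    if not boundary:
        return float(chi2.sf(dev, df)) if dev > 0 else 1.0
    upper = float(chi2.sf(dev, df)) if dev > 0 else 1.0
    if df == 1:
        lower = 1.0 if dev <= 0 else 0.0   # chi2 with 0 df: point mass at 0
    else:
        lower = float(chi2.sf(dev, df - 1)) if dev > 0 else 1.0
    return 0.5 * (lower + upper)


def select_changepoints(
    fit_for_cuts: Callable[[tuple[float, ...]], FitResult],
    candidate_cut_sets: Sequence[Sequence[float]],
    alpha: float = 0.05,
) -> tuple[tuple[float, ...], pd.DataFrame]:
    """Forward selection over nested baseline cut sets by LR tests.

    ``fit_for_cuts`` maps a cut tuple to a fitted model on the same
    data; candidate sets must be nested and ordered by size.  Cuts keep
    being added while the LR test against the previous set is
    significant at ``alpha``; the trail of tests is returned alongside
    the chosen cuts.
    """
    sets = [tuple(sorted(c)) for c in candidate_cut_sets]
    for a, b in zip(sets[:-1], sets[1:]):
        if not set(a) <= set(b):
            raise ValueError(f"candidate cut sets not nested: {a} vs {b}")
    if not sets or sets[0] != ():
        sets = [()] + sets
    chosen = sets[0]
    current = fit_for_cuts(chosen)
    trail = []
    for cand in sets[1:]:
        trial = fit_for_cuts(cand)
        df = len(cand) - len(chosen)
        p = lr_test(trial, current, df=df)
        keep = p < alpha
        trail.append({
            "cuts": str(list(cand)), "vs": str(list(chosen)), "df": df,
            "deviance": 2 * (trial.loglik - current.loglik), "p": p, "kept": keep,
        })
        if not keep:
            break
        chosen, current = cand, trial
    return chosen, pd.DataFrame(trail)


# ---------------------------------------------------------------------------
# joint (correlated bivariate frailty) model

@dataclass
class _JointData:
    pc: _Prepared
    pr: _Prepared
    persons: list[str]

    @property
    def n(self) -> int:
        return len(self.persons)


def _prepare_joint(rows_cess: pd.DataFrame, rows_rel: pd.DataFrame,
                   spec_c: ModelSpec, spec_r: ModelSpec) -> _JointData:
    persons = sorted(set(rows_cess["person_id"]) | set(rows_rel["person_id"]))
    pc = _prepare(rows_cess, spec_c, persons=persons)
    pr = _prepare(rows_rel, spec_r, persons=persons)
    return _JointData(pc, pr, persons)


def _mode_bivariate(Dc, Bc, Dr, Br, q11, q12, q22):
    u = np.zeros_like(Dc)
    v = np.zeros_like(Dr)
    for _ in range(200):
        eu, ev = np.exp(u), np.exp(v)
        g1 = Dc - Bc * eu - (q11 * u + q12 * v)
        g2 = Dr - Br * ev - (q12 * u + q22 * v)
        h11 = -Bc * eu - q11
        h22 = -Br * ev - q22
        h12 = -q12
        det = h11 * h22 - h12 * h12
        du = (h22 * g1 - h12 * g2) / det
        dv = (h11 * g2 - h12 * g1) / det
        du = np.clip(du, -5.0, 5.0)
        dv = np.clip(dv, -5.0, 5.0)
        u = u - du
        v = v - dv
        if max(np.max(np.abs(du)), np.max(np.abs(dv))) < 1e-12:
            break
    return u, v


def _joint_nll_grad(params: np.ndarray, data: _JointData, order: int,
                    rho_fixed: float | None, want_grad: bool = True):
    pc, pr = data.pc, data.pr
    kc, kr = pc.X.shape[1], pr.X.shape[1]
    theta_c = params[:kc]
    theta_r = params[kc:kc + kr]
    ls1, ls2 = params[kc + kr], params[kc + kr + 1]
    if rho_fixed is None:
        zpar = params[kc + kr + 2]
        rho = math.tanh(zpar)
    else:
        rho = float(rho_fixed)
    s1, s2v = math.exp(ls1), math.exp(ls2)
    om = 1.0 - rho * rho
    sq12 = math.sqrt(s1 * s2v)
    q11 = 1.0 / (s1 * om)
    q22 = 1.0 / (s2v * om)
    q12 = -rho / (sq12 * om)

    eta_c = pc.X @ theta_c
    eta_r = pr.X @ theta_r
    cc = pc.e * np.exp(eta_c)
    cr = pr.e * np.exp(eta_r)
    T1 = float(pc.d @ eta_c + pr.d @ eta_r)
    n = data.n
    Bc = np.bincount(pc.pid, weights=cc, minlength=n)
    Br = np.bincount(pr.pid, weights=cr, minlength=n)
    Dc, Dr = pc.D, pr.D

    uh, vh = _mode_bivariate(Dc, Bc, Dr, Br, q11, q12, q22)
    eu, ev = np.exp(uh), np.exp(vh)
    m11 = Bc * eu + q11
    m22 = Br * ev + q22
    m12 = np.full_like(m11, q12)
    det_m = m11 * m22 - m12 * m12
    # S = M^{-1}; Cholesky S = C C'
    s11 = m22 / det_m
    s12 = -m12 / det_m
    s22 = m11 / det_m
    c11 = np.sqrt(s11)
    c21 = s12 / c11
    c22 = np.sqrt(np.maximum(s22 - c21 * c21, 1e-300))
    detC = c11 * c22

    z, w = hermgauss(order)
    logw = np.log(w)
    ZA, ZB = np.meshgrid(z, z, indexing="ij")
    za = ZA.ravel()
    zb = ZB.ravel()
    lw = (logw[:, None] + logw[None, :]).ravel() + za * za + zb * zb

    U = uh[:, None] + _SQRT2 * c11[:, None] * za[None, :]
    V = vh[:, None] + _SQRT2 * (c21[:, None] * za[None, :] + c22[:, None] * zb[None, :])
    G = (Dc[:, None] * U - Bc[:, None] * np.exp(U)
         + Dr[:, None] * V - Br[:, None] * np.exp(V)
         - 0.5 * (q11 * U * U + 2.0 * q12 * U * V + q22 * V * V))
    A = lw[None, :] + G
    amax = A.max(axis=1)
    expa = np.exp(A - amax[:, None])
    ssum = expa.sum(axis=1)
    L = (math.log(2.0) + np.log(detC) - _LOG2PI
         - 0.5 * math.log(s1 * s2v * om) + amax + np.log(ssum))
    if not np.all(np.isfinite(L)):
        raise FloatingPointError(
            "non-finite 2-D quadrature value; try a higher order or rescaled data"
        )
    nll = -(T1 + float(L.sum()))
    if not want_grad:
        return nll, None

    p = expa / ssum[:, None]
    Eeu = (p * np.exp(U)).sum(axis=1)
    Eev = (p * np.exp(V)).sum(axis=1)
    grad_tc = pc.s - pc.X.T @ (cc * Eeu[pc.pid])
    grad_tr = pr.s - pr.X.T @ (cr * Eev[pr.pid])

    # variance-parameter scores: E_post[ d log phi2(u,v; Sigma) / d p ]
    # with d log phi = -1/2 tr(Q S_p) + 1/2 a' S_p a, a = Q w
    A1 = q11 * U + q12 * V
    A2 = q12 * U + q22 * V
    E11 = (p * A1 * A1).sum(axis=1)
    E12 = (p * A1 * A2).sum(axis=1)
    E22 = (p * A2 * A2).sum(axis=1)

    def score_for(Sp11, Sp12, Sp22):
        tr = q11 * Sp11 + 2.0 * q12 * Sp12 + q22 * Sp22
        quad = Sp11 * E11 + 2.0 * Sp12 * E12 + Sp22 * E22
        return float(np.sum(-0.5 * tr + 0.5 * quad))

    # dSigma/d log s1 = [[s1, rho*sq12/2], [., 0]]; likewise for log s2
    g_ls1 = score_for(s1, 0.5 * rho * sq12, 0.0)
    g_ls2 = score_for(0.0, 0.5 * rho * sq12, s2v)
    grads = [grad_tc, grad_tr, [g_ls1], [g_ls2]]
    if rho_fixed is None:
        # dSigma/dz = (1 - rho^2) * [[0, sq12], [sq12, 0]]
        g_z = score_for(0.0, om * sq12, 0.0)
        grads.append([g_z])
    grad = np.concatenate([np.asarray(g, float).ravel() for g in grads])
    return nll, -grad


def joint_marginal_loglik(rows_cess: pd.DataFrame, rows_rel: pd.DataFrame,
                          spec_c: ModelSpec, spec_r: ModelSpec,
                          theta_c: np.ndarray, theta_r: np.ndarray,
                          sigma2_c: float, sigma2_r: float, rho: float,
                          quad_order: int = 15) -> float:
    """Joint marginal log-likelihood at fixed parameter values."""
    data = _prepare_joint(rows_cess, rows_rel, spec_c, spec_r)
    params = np.concatenate([
        np.asarray(theta_c, float), np.asarray(theta_r, float),
        [math.log(sigma2_c), math.log(sigma2_r)],
    ])
    nll, _ = _joint_nll_grad(params, data, quad_order, rho_fixed=rho, want_grad=False)
    return -nll


def fit_joint(rows_cess: pd.DataFrame, rows_rel: pd.DataFrame,
              spec_c: ModelSpec, spec_r: ModelSpec,
              quad_order: int = 15, rho_fixed: float | None = None,
              se: bool = True) -> FitResult:
    """Joint cessation+relapse fit with correlated bivariate normal frailties.

    Starts from the two univariate fits; at ``rho_fixed=0`` the joint
    log-likelihood factorizes into the sum of the univariate marginal
    log-likelihoods (same quadrature order).
    """
    spec_c.validate()
    spec_r.validate()
    data = _prepare_joint(rows_cess, rows_rel, spec_c, spec_r)
    fc = fit(rows_cess, replace(spec_c, frailty="normal", quad_order=quad_order), se=False)
    fr = fit(rows_rel, replace(spec_r, frailty="normal", quad_order=quad_order), se=False)
    x0 = np.concatenate([
        fc.coef, fr.coef,
        [math.log(max(fc.sigma2, 1e-3)), math.log(max(fr.sigma2, 1e-3))],
        [] if rho_fixed is not None else [0.0],
    ])
    fun = lambda x: _joint_nll_grad(x, data, quad_order, rho_fixed)
    ll_init = -fun(x0)[0]
    res = minimize(fun, x0, jac=True, method="BFGS",
                   options={"gtol": spec_c.gtol, "maxiter": spec_c.maxiter})
    xhat = res.x
    ll = -float(res.fun)
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success) or grad_norm < 1e-3

    kc, kr = data.pc.X.shape[1], data.pr.X.shape[1]
    names = [f"cess:{nm}" for nm in data.pc.names] + [f"rel:{nm}" for nm in data.pr.names]
    se_all = np.full(xhat.size, np.nan)
    singular = False
    if se:
        h = _hess_from_grad(xhat, lambda x: fun(x)[1])
        try:
            cov = np.linalg.inv(h)
            diag = np.diag(cov)
            if np.any(diag <= 0):
                raise np.linalg.LinAlgError("non-positive variance")
            se_all = np.sqrt(diag)
        except np.linalg.LinAlgError:
            singular = True
            logger.warning("singular observed information in joint fit; SEs omitted")

    rho_hat = math.tanh(xhat[kc + kr + 2]) if rho_fixed is None else float(rho_fixed)
    return FitResult(
        names=names,
        coef=xhat[:kc + kr],
        se=se_all[:kc + kr],
        loglik=ll,
        loglik_init=ll_init,
        n_persons=data.n,
        n_rows=len(data.pc.d) + len(data.pr.d),
        converged=converged,
        grad_norm=grad_norm,
        spec=replace(spec_c, process="joint", cuts=spec_c.resolved_cuts(),
                     quad_order=quad_order),
        sigma2=math.exp(xhat[kc + kr]),
        sigma2_se_log=se_all[kc + kr],
        sigma2_rel=math.exp(xhat[kc + kr + 1]),
        sigma2_rel_se_log=se_all[kc + kr + 1],
        rho=rho_hat,
        rho_se_z=(se_all[kc + kr + 2] if rho_fixed is None else None),
        singular_information=singular,
        message=str(res.message),
    )
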
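"""Bayesian generative models for the source variables.

Five model families are provided:

* ``toy``        — Bernoulli group indicator + bivariate Normal (Z1, Z2);
* ``univariate`` — Normal regression of the derived outcome on group and age
  (quadratic in age, group×age interaction), for complete data;
* ``bivariate``  — correlated bivariate Normal for (log height, log weight)
  given group and age;
* ``bernoulli``  — Bernoulli risk model for a complete binary outcome
  (conjugate Beta posterior, sampled exactly);
* ``bsnmn``      — Bernoulli(sex) + truncated skew-Normal(gestational age) +
  two-component Normal mixture(head circumference): the microcephaly source
  model.

Missing binary entries (group, sex) are marginalized analytically inside the
likelihood; missing continuous entries are marginalized via the model's
marginal laws (bivariate-Normal marginals; 1-D quadrature over gestational
age).  After sampling, per-draw imputations are recovered from the exact full
conditionals, so imputed values are draws from the joint posterior of
parameters and missing data.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._bsnmn_kernel import bsnmn_loglik
from ._mcmc import IDENTITY, LOG, LOGIT, TANH, Param, run_ensemble, upper_shift
from .datamodel import MissingTable, PosteriorDraws
from .derive import GA_WINDOW, HCReference

__all__ = [
    "ToyParams",
    "UnivariateParams",
    "BivariateParams",
    "BernoulliParams",
    "BsNmNParams",
    "fit_toy_bivariate",
    "fit_univariate_normal",
    "fit_bivariate_normal",
    "fit_bernoulli",
    "fit_bsnmn",
    "implied_prior_outcome",
    "sample_toy_sources",
    "sample_growth_sources",
    "sample_bsnmn_sources",
    "skewnorm_location",
    "BSNMN_PRIOR",
]

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# parameter containers (used for generator truths and defaults)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyParams:
    zeta: float = 0.5
    muZ1A: float = 0.5
    muZ2A: float = 1.7
    muZ1B: float = 1.5
    muZ2B: float = 1.8
    sigZ1: float = 1.0
    sigZ2: float = 1.0
    rho: float = 0.2

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class UnivariateParams:
    beta0: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0
    beta4: float = 0.0
    sigma: float = 1.0
    pi: float = 0.5

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class BivariateParams:
    """Log-height (alpha) and log-weight (gamma) regressions on [1,x,a,xa,a²]."""

    alpha0: float = 4.30
    alpha1: float = 0.01
    alpha2: float = 0.090
    alpha3: float = 0.0
    alpha4: float = -0.0022
    gamma0: float = 2.20
    gamma1: float = 0.03
    gamma2: float = 0.135
    gamma3: float = 0.0
    gamma4: float = -0.0012
    tauZ1: float = 0.04
    tauZ2: float = 0.15
    rho: float = 0.5
    pi: float = 0.09

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class BernoulliParams:
    theta: float = 0.1

    def to_dict(self) -> dict:
        return {"theta": self.theta}


@dataclass(frozen=True)
class BsNmNParams:
    """Sex ~ Bernoulli(0.5); (ga−39) ~ skew-Normal(mean μ, scale σ, slant ω)
    truncated to the gestational-age window; hc | sex, ga ~ q·Normal(curve, ζ1)
    + (1−q)·Normal(curve + κ, ζ2) with curve = β0+β1·sex+β2·Δ+β3·Δ², Δ=ga−39.
    κ ≤ −1 is the affected-component mean shift (identifiability constraint).
    """

    mu: float = 0.0
    sigma: float = 2.5
    omega: float = -2.5
    beta0: float = 33.912
    beta1: float = -0.450
    beta2: float = 0.399
    beta3: float = -0.016
    zeta1: float = 1.3
    zeta2: float = 2.5
    kappa: float = -6.0
    q: float = 0.894

    def __post_init__(self) -> None:
        if self.kappa > -1:
            raise ValueError("kappa must be <= -1")
        for s in ("sigma", "zeta1", "zeta2"):
            if getattr(self, s) <= 0:
                raise ValueError(f"{s} must be positive")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# prior density helpers (vectorized over the constrained value)
# ---------------------------------------------------------------------------


def _norm_lp(mean, sd):
    return lambda x: -0.5 * ((x - mean) / sd) ** 2 - np.log(sd) - 0.5 * _LOG2PI


def _expon_lp(rate=1.0):
    return lambda x: np.where(x > 0, np.log(rate) - rate * x, -np.inf)


def _unif_lp(lo, hi):
    c = -np.log(hi - lo)
    return lambda x: np.where((x >= lo) & (x <= hi), c, -np.inf)


def _invgamma_lp(a, b):
    return lambda x: np.where(x > 0, stats.invgamma.logpdf(x, a, scale=b), -np.inf)


def _trunc_norm_upper_lp(mean, sd, upper):
    logZ = stats.norm.logcdf((upper - mean) / sd)
    f = _norm_lp(mean, sd)
    return lambda x: np.where(x <= upper, f(x) - logZ, -np.inf)


def _init_normal(center, scale):
    return lambda rng, k: center + scale * rng.standard_normal(k)


def _init_lognormal(center, scale=0.3):
    return lambda rng, k: center * np.exp(scale * rng.standard_normal(k))


def _init_uniform(lo, hi):
    return lambda rng, k: rng.uniform(lo, hi, k)


def _binary_logpmf(x, p):
    # x (r,), p (K,) -> (K,)
    ones = float(np.sum(x))
    zeros = float(len(x) - ones)
    return ones * np.log(p) + zeros * np.log1p(-p)


def _norm_logpdf(x, mean, sd):
    return -0.5 * ((x - mean) / sd) ** 2 - np.log(sd) - 0.5 * _LOG2PI


def _bvn_logpdf(d1, d2, s1, s2, rho):
    """Bivariate normal logpdf of residuals d1, d2 (broadcastable) given scales."""
    om = 1.0 - rho**2
    z = (d1 / s1) ** 2 - 2.0 * rho * (d1 / s1) * (d2 / s2) + (d2 / s2) ** 2
    return -_LOG2PI - np.log(s1 * s2) - 0.5 * np.log(om) - z / (2.0 * om)


def _empty_imp(M: int) -> pd.DataFrame:
    return pd.DataFrame(index=range(M))


# ---------------------------------------------------------------------------
# toy model
# ---------------------------------------------------------------------------

TOY_PRIOR = {"mean_loc": 0.0, "mean_sd": 10.0, "sd_rate": 1.0}


def _toy_params(priors: Mapping | None, moments: Mapping | None = None):
    p = dict(TOY_PRIOR, **(priors or {}))
    mlp = _norm_lp(p["mean_loc"], p["mean_sd"])
    mo = moments or {}

    def _mean_init(name):
        c = mo.get(name)
        if c is None:
            return _init_normal(p["mean_loc"], p["mean_sd"])
        return _init_normal(c, 0.3)

    def _sd_init(name):
        return _init_lognormal(mo.get(name, 1.0), 0.1)

    return [
        Param("zeta", LOGIT, _unif_lp(0, 1), _init_uniform(0.2, 0.8)),
        Param("muZ1A", IDENTITY, mlp, _mean_init("muZ1A")),
        Param("muZ2A", IDENTITY, mlp, _mean_init("muZ2A")),
        Param("muZ1B", IDENTITY, mlp, _mean_init("muZ1B")),
        Param("muZ2B", IDENTITY, mlp, _mean_init("muZ2B")),
        Param("sigZ1", LOG, _expon_lp(p["sd_rate"]), _sd_init("sigZ1")),
        Param("sigZ2", LOG, _expon_lp(p["sd_rate"]), _sd_init("sigZ2")),
        Param("rho", TANH, _unif_lp(-1, 1), _init_uniform(-0.4, 0.4)),
    ]


def _toy_z_loglik(z1, z2, m1, m2, s1, s2, rho):
    """(K,) log-density of one row's observed z-pattern under given group means."""
    if not np.isnan(z1) and not np.isnan(z2):
        return _bvn_logpdf(z1 - m1, z2 - m2, s1, s2, rho)
    if not np.isnan(z1):
        return _norm_logpdf(z1, m1, s1)
    if not np.isnan(z2):
        return _norm_logpdf(z2, m2, s2)
    return np.zeros_like(m1)


def fit_toy_bivariate(
    table: MissingTable,
    priors: Mapping | None = None,
    M: int = 2000,
    seed: int = 0,
    warmup: int = 1000,
) -> PosteriorDraws:
    """Fit the toy model: X ~ Bernoulli(ζ), (Z1,Z2) | group ~ bivariate Normal.

    Missing X entries are marginalized in the likelihood and imputed per draw;
    missing Z entries contribute their Normal marginals and are likewise
    imputed from the conditional Normal given the draw.
    """
    d = table.data
    x = d["X"].to_numpy(float)
    z1 = d["Z1"].to_numpy(float)
    z2 = d["Z2"].to_numpy(float)
    n = len(d)
    xobs = ~np.isnan(x)

    # pattern groups among X-observed rows, per group
    def _group_stats(sel):
        both = sel & ~np.isnan(z1) & ~np.isnan(z2)
        only1 = sel & ~np.isnan(z1) & np.isnan(z2)
        only2 = sel & np.isnan(z1) & ~np.isnan(z2)
        return both, only1, only2

    pat = {
        "A": _group_stats(xobs & (x == 0)),
        "B": _group_stats(xobs & (x == 1)),
    }
    xmis_idx = np.flatnonzero(~xobs)

    # data-informed walker starting moments (None where a group is empty)
    moments = {}
    for g, zv in (("muZ1A", z1[xobs & (x == 0)]), ("muZ2A", z2[xobs & (x == 0)]),
                  ("muZ1B", z1[xobs & (x == 1)]), ("muZ2B", z2[xobs & (x == 1)])):
        ok = ~np.isnan(zv)
        if ok.any():
            moments[g] = float(np.mean(zv[ok]))
    for nm, zv in (("sigZ1", z1), ("sigZ2", z2)):
        ok = ~np.isnan(zv)
        if ok.sum() >= 3:
            moments[nm] = float(np.std(zv[ok])) or 1.0

    def log_lik(P: pd.DataFrame) -> np.ndarray:
        zeta = P["zeta"].to_numpy()
        s1 = P["sigZ1"].to_numpy()
        s2 = P["sigZ2"].to_numpy()
        rho = P["rho"].to_numpy()
        means = {
            "A": (P["muZ1A"].to_numpy(), P["muZ2A"].to_numpy()),
            "B": (P["muZ1B"].to_numpy(), P["muZ2B"].to_numpy()),
        }
        ll = _binary_logpmf(x[xobs], zeta)
        for g, (both, only1, only2) in pat.items():
            m1, m2 = means[g]
            if both.any():
                ll = ll + _bvn_logpdf(
                    z1[both][None, :] - m1[:, None],
                    z2[both][None, :] - m2[:, None],
                    s1[:, None], s2[:, None], rho[:, None],
                ).sum(axis=1)
            if only1.any():
                ll = ll + _norm_logpdf(z1[only1][None, :], m1[:, None], s1[:, None]).sum(axis=1)
            if only2.any():
                ll = ll + _norm_logpdf(z2[only2][None, :], m2[:, None], s2[:, None]).sum(axis=1)
        for i in xmis_idx:
            lA = _toy_z_loglik(z1[i], z2[i], means["A"][0], means["A"][1], s1, s2, rho)
            lB = _toy_z_loglik(z1[i], z2[i], means["B"][0], means["B"][1], s1, s2, rho)
            ll = ll + np.logaddexp(np.log(zeta) + lB, np.log1p(-zeta) + lA)
        return ll

    draws, diag = run_ensemble(_toy_params(priors, moments), log_lik, M, seed,
                               warmup=warmup, keep_steps=1200)

    # per-draw imputation from full conditionals
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1707]))
    zeta = draws["zeta"].to_numpy()
    s1 = draws["sigZ1"].to_numpy()
    s2 = draws["sigZ2"].to_numpy()
    rho = draws["rho"].to_numpy()
    mu = {
        0: (draws["muZ1A"].to_numpy(), draws["muZ2A"].to_numpy()),
        1: (draws["muZ1B"].to_numpy(), draws["muZ2B"].to_numpy()),
    }
    imp_x: dict[str, np.ndarray] = {}
    x_draws: dict[int, np.ndarray] = {}
    for i in xmis_idx:
        lA = _toy_z_loglik(z1[i], z2[i], mu[0][0], mu[0][1], s1, s2, rho)
        lB = _toy_z_loglik(z1[i], z2[i], mu[1][0], mu[1][1], s1, s2, rho)
        p1 = 1.0 / (1.0 + np.exp(np.log1p(-zeta) + lA - np.log(zeta) - lB))
        xi = (rng.random(M) < p1).astype(float)
        imp_x[f"X[{d.index[i]}]"] = xi
        x_draws[i] = xi
    imp_z: dict[str, np.ndarray] = {}
    for i in range(n):
        m1z, m2z = np.isnan(z1[i]), np.isnan(z2[i])
        if not (m1z or m2z):
            continue
        xi = x_draws.get(i, np.full(M, x[i]))
        m1 = np.where(xi == 1, mu[1][0], mu[0][0])
        m2 = np.where(xi == 1, mu[1][1], mu[0][1])
        if m1z and m2z:
            e1 = rng.standard_normal(M)
            e2 = rng.standard_normal(M)
            imp_z[f"Z1[{d.index[i]}]"] = m1 + s1 * e1
            imp_z[f"Z2[{d.index[i]}]"] = m2 + s2 * (rho * e1 + np.sqrt(1 - rho**2) * e2)
        elif m1z:
            cm = m1 + rho * s1 / s2 * (z2[i] - m2)
            imp_z[f"Z1[{d.index[i]}]"] = cm + s1 * np.sqrt(1 - rho**2) * rng.standard_normal(M)
        else:
            cm = m2 + rho * s2 / s1 * (z1[i] - m1)
            imp_z[f"Z2[{d.index[i]}]"] = cm + s2 * np.sqrt(1 - rho**2) * rng.standard_normal(M)

    return PosteriorDraws(
        params=draws,
        model="toy",
        imputed_expl=pd.DataFrame(imp_x) if imp_x else _empty_imp(M),
        imputed_source=pd.DataFrame(imp_z) if imp_z else _empty_imp(M),
        diagnostics=diag,
    )


def sample_toy_sources(params: Mapping, S: int, rng: np.random.Generator, x=None):
    """Forward-simulate S rows of (Z1, Z2) from the toy model.

    ``x`` fixes the group (0/1); None draws X ~ Bernoulli(ζ) per row.
    """
    if x is None:
        xv = (rng.random(S) < params["zeta"]).astype(float)
    else:
        xv = np.full(S, float(x))
    m1 = np.where(xv == 1, params["muZ1B"], params["muZ1A"])
    m2 = np.where(xv == 1, params["muZ2B"], params["muZ2A"])
    s1, s2, rho = params["sigZ1"], params["sigZ2"], params["rho"]
    e1 = rng.standard_normal(S)
    e2 = rng.standard_normal(S)
    z1 = m1 + s1 * e1
    z2 = m2 + s2 * (rho * e1 + np.sqrt(1 - rho**2) * e2)
    return pd.DataFrame({"Z1": z1, "Z2": z2, "X": xv})


# ---------------------------------------------------------------------------
# univariate normal regression (complete data)
# ---------------------------------------------------------------------------


def _design(x, a):
    return np.column_stack([np.ones_like(a), x, a, x * a, a * a])


def _reg_params(names, y, D, sd_name="sigma"):
    """Normal(0,1) coefficient priors with OLS-informed walker initialization.

    Walkers start at the least-squares solution jittered by twice its standard
    errors, so the whole ensemble begins inside the typical set (jitter
    proportional to the coefficient magnitude would catapult the quadratic-age
    term and strand walkers in a large-variance local mode).
    """
    p = D.shape[1]
    if len(y) >= p + 2:
        coef, *_ = np.linalg.lstsq(D, y, rcond=None)
        resid_sd = float(np.std(y - D @ coef)) or 1.0
        cov = np.linalg.inv(D.T @ D + 1e-10 * np.eye(p))
        se = resid_sd * np.sqrt(np.diag(cov))
    else:
        coef = np.zeros(p)
        resid_sd = 1.0
        se = np.ones(p)
    out = [
        Param(nm, IDENTITY, _norm_lp(0.0, 1.0), _init_normal(c, 2.0 * s + 1e-6))
        for nm, c, s in zip(names, coef, se)
    ]
    out.append(Param(sd_name, LOG, _expon_lp(1.0), _init_lognormal(resid_sd, 0.05)))
    return out, coef, resid_sd


def fit_univariate_normal(
    table: MissingTable,
    priors: Mapping | None = None,
    M: int = 2000,
    seed: int = 0,
    warmup: int = 1000,
    x_col: str = "X",
    a_col: str = "A",
) -> PosteriorDraws:
    """Normal regression of the derived outcome on [1, x, a, xa, a²]; X ~ Bern(π).

    Requires a complete table (complete-case or an imputed completed dataset);
    age enters untransformed with standard-Normal coefficient priors.
    """
    if table.mask.to_numpy().any():
        raise ValueError(
            "fit_univariate_normal requires complete data; impute or take complete cases first"
        )
    y_col = table.derived_name
    if y_col is None:
        raise ValueError("table has no derived outcome column")
    y = table.data[y_col].to_numpy(float)
    x = table.data[x_col].to_numpy(float)
    a = table.data[a_col].to_numpy(float)
    D = _design(x, a)
    n = len(y)
    names = ["beta0", "beta1", "beta2", "beta3", "beta4"]
    params, _, _ = _reg_params(names, y, D)
    params.append(Param("pi", LOGIT, _unif_lp(0, 1), _init_uniform(0.05, 0.5)))

    def log_lik(P: pd.DataFrame) -> np.ndarray:
        B = P[names].to_numpy()  # (K,5)
        sig = P["sigma"].to_numpy()
        mean = D @ B.T  # (n,K)
        resid = y[:, None] - mean
        ll = -n * np.log(sig) - 0.5 * n * _LOG2PI - (resid**2).sum(axis=0) / (2 * sig**2)
        return ll + _binary_logpmf(x, P["pi"].to_numpy())

    draws, diag = run_ensemble(params, log_lik, M, seed, warmup=warmup,
                               keep_steps=800)
    return PosteriorDraws(params=draws, model="univariate", imputed_expl=_empty_imp(M),
                          imputed_source=_empty_imp(M), diagnostics=diag)


# ---------------------------------------------------------------------------
# bivariate normal model for (log height, log weight)
# ---------------------------------------------------------------------------


def fit_bivariate_normal(
    table: MissingTable,
    priors: Mapping | None = None,
    M: int = 2000,
    seed: int = 0,
    warmup: int = 1000,
    x_col: str = "X",
    a_col: str = "A",
    height_col: str = "height",
    weight_col: str = "weight",
) -> PosteriorDraws:
    """Correlated Normal model for (log height, log weight) given group and age.

    Age must be fully observed; the binary group indicator may be missing
    (marginalized, then imputed per draw); missing heights/weights contribute
    their Normal marginals and are imputed from conditional Normals per draw
    (reported on the natural cm/kg scale).
    """
    d = table.data
    a = d[a_col].to_numpy(float)
    if np.isnan(a).any():
        raise ValueError("age must be fully observed")
    x = d[x_col].to_numpy(float)
    h = d[height_col].to_numpy(float)
    w = d[weight_col].to_numpy(float)
    if np.nanmin(h) <= 0 or np.nanmin(w) <= 0:
        raise ValueError("height and weight must be positive (modelled on the log scale)")
    u = np.log(h)
    v = np.log(w)
    n = len(d)
    xobs = ~np.isnan(x)

    anames = [f"alpha{j}" for j in range(5)]
    gnames = [f"gamma{j}" for j in range(5)]
    cc = xobs & ~np.isnan(u) & ~np.isnan(v)
    pa, ca, _ = _reg_params(anames, u[cc], _design(x[cc], a[cc]), sd_name="tauZ1")
    pg, cg, _ = _reg_params(gnames, v[cc], _design(x[cc], a[cc]), sd_name="tauZ2")
    params = pa + pg + [
        Param("rho", TANH, _unif_lp(-1, 1), _init_uniform(0.2, 0.6)),
        Param("pi", LOGIT, _unif_lp(0, 1), _init_uniform(0.05, 0.2)),
    ]

    D0 = _design(np.zeros(n), a)
    D1 = _design(np.ones(n), a)
    uobs = ~np.isnan(u)
    vobs = ~np.isnan(v)
    pat_both = uobs & vobs
    pat_u = uobs & ~vobs
    pat_v = ~uobs & vobs
    xmis_idx = np.flatnonzero(~xobs)

    def _rowwise_ll(P, DX):
        """(K, n) log-density of each row's observed (u, v) pattern given design DX."""
        A = P[anames].to_numpy()
        G = P[gnames].to_numpy()
        t1 = P["tauZ1"].to_numpy()[:, None]
        t2 = P["tauZ2"].to_numpy()[:, None]
        r = P["rho"].to_numpy()[:, None]
        mu_u = (DX @ A.T).T  # (K, n)
        mu_v = (DX @ G.T).T
        out = np.zeros((len(P), n))
        if pat_both.any():
            out[:, pat_both] = _bvn_logpdf(
                u[pat_both][None, :] - mu_u[:, pat_both],
                v[pat_both][None, :] - mu_v[:, pat_both], t1, t2, r)
        if pat_u.any():
            out[:, pat_u] = _norm_logpdf(u[pat_u][None, :], mu_u[:, pat_u], t1)
        if pat_v.any():
            out[:, pat_v] = _norm_logpdf(v[pat_v][None, :], mu_v[:, pat_v], t2)
        return out

    Dx = _design(np.where(xobs, x, 0.0), a)

    def log_lik(P: pd.DataFrame) -> np.ndarray:
        pi = P["pi"].to_numpy()
        ll = _binary_logpmf(x[xobs], pi)
        lx = _rowwise_ll(P, Dx)  # valid for x-observed rows
        ll = ll + lx[:, xobs].sum(axis=1)
        if len(xmis_idx):
            l0 = _rowwise_ll(P, D0)[:, xmis_idx]
            l1 = _rowwise_ll(P, D1)[:, xmis_idx]
            ll = ll + np.logaddexp(
                np.log(pi)[:, None] + l1, np.log1p(-pi)[:, None] + l0
            ).sum(axis=1)
        return ll

    draws, diag = run_ensemble(params, log_lik, M, seed, warmup=warmup,
                               keep_steps=1200)

    # per-draw imputation
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB1F]))
    A = draws[anames].to_numpy()
    G = draws[gnames].to_numpy()
    t1 = draws["tauZ1"].to_numpy()
    t2 = draws["tauZ2"].to_numpy()
    r = draws["rho"].to_numpy()
    pi = draws["pi"].to_numpy()
    imp_x: dict[str, np.ndarray] = {}
    x_draws: dict[int, np.ndarray] = {}
    for i in xmis_idx:
        d0 = _design(np.zeros(1), a[i : i + 1])[0]
        d1 = _design(np.ones(1), a[i : i + 1])[0]

        def _patt_ll(dd):
            mu_u = A @ dd
            mu_v = G @ dd
            if pat_both[i]:
                return _bvn_logpdf(u[i] - mu_u, v[i] - mu_v, t1, t2, r)
            if pat_u[i]:
                return _norm_logpdf(u[i], mu_u, t1)
            if pat_v[i]:
                return _norm_logpdf(v[i], mu_v, t2)
            return np.zeros(M)

        l0, l1 = _patt_ll(d0), _patt_ll(d1)
        p1 = 1.0 / (1.0 + np.exp(np.log1p(-pi) + l0 - np.log(pi) - l1))
        xi = (rng.random(M) < p1).astype(float)
        imp_x[f"{x_col}[{d.index[i]}]"] = xi
        x_draws[i] = xi
    imp_s: dict[str, np.ndarray] = {}
    for i in range(n):
        mu_m, mv_m = not uobs[i], not vobs[i]
        if not (mu_m or mv_m):
            continue
        xi = x_draws.get(i, np.full(M, x[i]))
        dd = _design(xi, np.full(M, a[i]))  # (M,5)
        mu_u = (dd * A).sum(axis=1)
        mu_v = (dd * G).sum(axis=1)
        if mu_m and mv_m:
            e1 = rng.standard_normal(M)
            e2 = rng.standard_normal(M)
            ui = mu_u + t1 * e1
            vi = mu_v + t2 * (r * e1 + np.sqrt(1 - r**2) * e2)
            imp_s[f"{height_col}[{d.index[i]}]"] = np.exp(ui)
            imp_s[f"{weight_col}[{d.index[i]}]"] = np.exp(vi)
        elif mu_m:
            cm = mu_u + r * t1 / t2 * (v[i] - mu_v)
            ui = cm + t1 * np.sqrt(1 - r**2) * rng.standard_normal(M)
            imp_s[f"{height_col}[{d.index[i]}]"] = np.exp(ui)
        else:
            cm = mu_v + r * t2 / t1 * (u[i] - mu_u)
            vi = cm + t2 * np.sqrt(1 - r**2) * rng.standard_normal(M)
            imp_s[f"{weight_col}[{d.index[i]}]"] = np.exp(vi)

    return PosteriorDraws(
        params=draws,
        model="bivariate",
        imputed_expl=pd.DataFrame(imp_x) if imp_x else _empty_imp(M),
        imputed_source=pd.DataFrame(imp_s) if imp_s else _empty_imp(M),
        diagnostics=diag,
    )


def sample_growth_sources(params: Mapping, S: int, rng: np.random.Generator, x, ages):
    """Forward-simulate S rows of (height, weight) at group ``x`` and given ages."""
    ages = np.asarray(ages, dtype=float)
    dd = _design(np.full(S, float(x)), ages)
    A = np.array([params[f"alpha{j}"] for j in range(5)])
    G = np.array([params[f"gamma{j}"] for j in range(5)])
    t1, t2, rho = params["tauZ1"], params["tauZ2"], params["rho"]
    e1 = rng.standard_normal(S)
    e2 = rng.standard_normal(S)
    u = dd @ A + t1 * e1
    v = dd @ G + t2 * (rho * e1 + np.sqrt(1 - rho**2) * e2)
    return pd.DataFrame({"height": np.exp(u), "weight": np.exp(v), "A": ages})


# ---------------------------------------------------------------------------
# Bernoulli risk model (conjugate)
# ---------------------------------------------------------------------------


def fit_bernoulli(
    table: MissingTable,
    prior_a: float = 1.26,
    prior_b: float = 2.32,
    M: int = 5000,
    seed: int = 0,
) -> PosteriorDraws:
    """Bernoulli(θ) model for a complete binary outcome with a Beta(a, b) prior.

    The posterior is conjugate — Beta(a + Σy, b + n − Σy) — and is sampled
    exactly (iid), so the draws agree with the closed form by construction.
    """
    y_col = table.derived_name
    if y_col is None:
        raise ValueError("table has no derived outcome column")
    y = table.data[y_col].to_numpy(float)
    if np.isnan(y).any():
        raise ValueError("fit_bernoulli requires a complete outcome column")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary (0/1)")
    n, s = len(y), float(y.sum())
    rng = np.random.default_rng(seed)
    theta = rng.beta(prior_a + s, prior_b + n - s, size=M)
    diag = {
        "rhat": {"theta": 1.0},
        "ess": {"theta": float(M)},
        "warnings": [],
        "exact": True,
        "posterior": ("beta", prior_a + s, prior_b + n - s),
    }
    return PosteriorDraws(params=pd.DataFrame({"theta": theta}), model="bernoulli",
                          imputed_expl=_empty_imp(M), imputed_source=_empty_imp(M),
                          diagnostics=diag)


# ---------------------------------------------------------------------------
# BsNmN model (sex / gestational age / head circumference)
# ---------------------------------------------------------------------------

BSNMN_PRIOR = {
    "mu": (0.0, 0.1),
    "sigma": (2.0, 2.0),        # inv-Gamma(shape, scale)
    "omega": (0.0, 2.0),
    "beta0": (33.912, 0.1),
    "beta1": (-0.450, 0.1),
    "beta2": (0.399, 0.1),
    "beta3": (-0.016, 0.1),
    "zeta1": (2.0, 2.0),        # inv-Gamma
    "zeta2": (2.0, 2.0),        # inv-Gamma
    "kappa": (-2.0, 2.0, -1.0),  # Normal(mean, sd) truncated above at -1
    "q": (0.0, 1.0),
}

_GA_GRID_SIZE = 61


def pack_bsnmn_data(s, g, h, grid, tw):
    """Pack a (sex, ga, hc) table into the arrays the compiled likelihood expects.

    Sex is recoded 2.0 where missing (marginalized at probability ½ inside the
    likelihood); rows are split into observed-ga and quadrature groups.
    """
    sobs, gobs, hobs = ~np.isnan(s), ~np.isnan(g), ~np.isnan(h)
    scode = np.where(sobs, s, 2.0)
    i2 = gobs & hobs
    i3 = ~gobs & hobs
    return (
        np.ascontiguousarray(g[gobs]),
        np.ascontiguousarray(g[i2]),
        np.ascontiguousarray(h[i2]),
        np.ascontiguousarray(scode[i2]),
        np.ascontiguousarray(h[i3]),
        np.ascontiguousarray(scode[i3]),
        float(sobs.sum()),
        np.ascontiguousarray(grid),
        np.ascontiguousarray(tw),
    )


def skewnorm_location(mu, sigma, omega):
    """Location ξ such that the skew-Normal(ξ, σ, ω) has mean μ."""
    delta = omega / np.sqrt(1.0 + omega**2)
    return mu - sigma * delta * np.sqrt(2.0 / np.pi)


def _ga_lognorm(mu, sigma, omega, window=GA_WINDOW):
    """Log normalizing constant of the [lo, hi]-truncated ga law (array params)."""
    loc = 39.0 + skewnorm_location(mu, sigma, omega)
    cdf_hi = stats.skewnorm.cdf(window[1], omega, loc=loc, scale=sigma)
    cdf_lo = stats.skewnorm.cdf(window[0], omega, loc=loc, scale=sigma)
    return np.log(np.maximum(cdf_hi - cdf_lo, 1e-300))


def _ga_logpdf(g, mu, sigma, omega, lognorm):
    """Truncated skew-Normal logpdf; g and params broadcast together."""
    loc = 39.0 + skewnorm_location(mu, sigma, omega)
    t = (g - loc) / sigma
    return (
        np.log(2.0) - np.log(sigma) - 0.5 * t**2 - 0.5 * _LOG2PI
        + stats.norm.logcdf(omega * t) - lognorm
    )


def _mix_logpdf(h, curve, kappa, z1s, z2s, q):
    """Two-component Normal mixture logpdf (all arrays broadcastable)."""
    return np.logaddexp(
        np.log(q) + _norm_logpdf(h, curve, z1s),
        np.log1p(-q) + _norm_logpdf(h, curve + kappa, z2s),
    )


def _bsnmn_params(priors: Mapping | None, data_init: Mapping | None = None):
    p = {**BSNMN_PRIOR, **(priors or {})}
    di = data_init or {}
    ga_mu = di.get("ga_mean", 39.0) - 39.0
    ga_sd = di.get("ga_sd", 1.5)
    return [
        Param("mu", IDENTITY, _norm_lp(*p["mu"]), _init_normal(p["mu"][0], p["mu"][1])),
        Param("sigma", LOG, _invgamma_lp(*p["sigma"]), _init_lognormal(max(ga_sd * 1.4, 0.5), 0.2)),
        Param("omega", IDENTITY, _norm_lp(*p["omega"]), _init_normal(-2.0, 1.0)),
        Param("beta0", IDENTITY, _norm_lp(*p["beta0"]), _init_normal(*p["beta0"])),
        Param("beta1", IDENTITY, _norm_lp(*p["beta1"]), _init_normal(*p["beta1"])),
        Param("beta2", IDENTITY, _norm_lp(*p["beta2"]), _init_normal(*p["beta2"])),
        Param("beta3", IDENTITY, _norm_lp(*p["beta3"]), _init_normal(*p["beta3"])),
        Param("zeta1", LOG, _invgamma_lp(*p["zeta1"]), _init_lognormal(1.3, 0.2)),
        Param("zeta2", LOG, _invgamma_lp(*p["zeta2"]), _init_lognormal(2.0, 0.2)),
        Param("kappa", upper_shift(-1.0), _trunc_norm_upper_lp(*p["kappa"]),
              _init_uniform(-4.0, -1.5)),
        Param("q", LOGIT, _unif_lp(*p["q"]), _init_uniform(0.6, 0.95)),
    ] , p


def fit_bsnmn(
    table: MissingTable,
    priors: Mapping | None = None,
    M: int = 5000,
    seed: int = 0,
    warmup: int = 1000,
    window=GA_WINDOW,
    grid_size: int = _GA_GRID_SIZE,
    keep_steps: int | None = None,
) -> PosteriorDraws:
    """Fit the Bernoulli + skew-Normal + mixture-Normal source model.

    Missing sex is marginalized analytically; a missing gestational age with an
    observed head circumference is marginalized by trapezoid quadrature over
    the ga window; both are imputed from full conditionals per retained draw.
    A posterior for the mixture weight q piling at its boundary triggers an
    identifiability warning in the diagnostics.
    """
    d = table.data
    s = d["sex"].to_numpy(float)
    g = d["ga"].to_numpy(float)
    h = d["hc"].to_numpy(float)
    sobs, gobs, hobs = ~np.isnan(s), ~np.isnan(g), ~np.isnan(h)

    grid = np.linspace(window[0], window[1], grid_size)
    dgrid = grid - 39.0
    tw = np.gradient(grid)  # trapezoid weights
    log_tw = np.log(tw)

    packed = pack_bsnmn_data(s, g, h, grid, tw)
    n_sex_obs = int(sobs.sum())

    data_init = {}
    if gobs.any():
        data_init = {"ga_mean": float(np.mean(g[gobs])), "ga_sd": float(np.std(g[gobs]))}
    params, _ = _bsnmn_params(priors, data_init)
    order = [p.name for p in params]

    def log_lik(P: pd.DataFrame) -> np.ndarray:
        return bsnmn_loglik(np.ascontiguousarray(P[order].to_numpy(float)), *packed)

    nwalkers = max(2 * len(params) + 2, 24)
    if keep_steps is None:
        keep_steps = 1250
    draws, diag = run_ensemble(params, log_lik, M, seed, warmup=warmup,
                               nwalkers=nwalkers, keep_steps=keep_steps)

    if (draws["q"] > 0.995).mean() > 0.5 or (draws["q"] < 0.005).mean() > 0.5:
        msg = "identifiability warning: posterior mass of q piles at the boundary"
        diag["warnings"].append(msg)
        _warnings.warn(msg, UserWarning, stacklevel=2)

    # ---- per-draw imputation from full conditionals ----
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB5]))
    imp: dict[str, np.ndarray] = {}
    mis_rows = np.flatnonzero(~sobs | ~gobs | ~hobs)
    if len(mis_rows):
        P = draws
        mu = P["mu"].to_numpy(); sg = P["sigma"].to_numpy(); om = P["omega"].to_numpy()
        b = [P[f"beta{j}"].to_numpy() for j in range(4)]
        z1s = P["zeta1"].to_numpy(); z2s = P["zeta2"].to_numpy()
        kp = P["kappa"].to_numpy(); q = P["q"].to_numpy()
        lognorm = _ga_lognorm(mu, sg, om, window)
        lga_grid = _ga_logpdf(grid[None, :], mu[:, None], sg[:, None], om[:, None],
                              lognorm[:, None]) + log_tw[None, :]  # (M, G)
        half_cell = 0.5 * (grid[1] - grid[0])

        def _curve(sex_vals, dd):
            # sex_vals scalar or (M,), dd scalar or (M,) -> (M,) mixture mean curve
            return b[0] + b[1] * sex_vals + b[2] * dd + b[3] * dd**2

        def _curve_grid(sex_vals):
            # sex_vals scalar or (M,1); over the ga grid -> (M, G)
            return (b[0][:, None] + b[1][:, None] * sex_vals
                    + b[2][:, None] * dgrid[None, :]
                    + b[3][:, None] * dgrid[None, :] ** 2)

        def _sample_mix(mean, rng):
            comp2 = rng.random(M) >= q
            sd = np.where(comp2, z2s, z1s)
            shift = np.where(comp2, kp, 0.0)
            return mean + shift + sd * rng.standard_normal(M)

        for i in mis_rows:
            si, gi, hi = s[i], g[i], h[i]
            s_i = np.full(M, si)
            if np.isnan(si):
                if not np.isnan(gi) and not np.isnan(hi):
                    dd = gi - 39.0
                    l0 = _mix_logpdf(hi, _curve(0.0, dd), kp, z1s, z2s, q)
                    l1 = _mix_logpdf(hi, _curve(1.0, dd), kp, z1s, z2s, q)
                    p1 = 1.0 / (1.0 + np.exp(l0 - l1))
                elif np.isnan(gi) and not np.isnan(hi):
                    lw = []
                    for sv in (0.0, 1.0):
                        lmix = _mix_logpdf(hi, _curve_grid(sv), kp[:, None],
                                           z1s[:, None], z2s[:, None], q[:, None])
                        lw.append(logsumexp_lastaxis(lga_grid + lmix))
                    p1 = 1.0 / (1.0 + np.exp(lw[0] - lw[1]))
                else:
                    p1 = np.full(M, 0.5)
                s_i = (rng.random(M) < p1).astype(float)
                imp[f"sex[{d.index[i]}]"] = s_i
            g_i = np.full(M, gi)
            if np.isnan(gi):
                lw = lga_grid.copy()
                if not np.isnan(hi):
                    curve = _curve_grid(s_i[:, None])
                    lw = lw + _mix_logpdf(hi, curve, kp[:, None], z1s[:, None],
                                          z2s[:, None], q[:, None])
                lw = lw - lw.max(axis=1, keepdims=True)
                wts = np.exp(lw)
                wts /= wts.sum(axis=1, keepdims=True)
                cells = (wts.cumsum(axis=1) < rng.random(M)[:, None]).sum(axis=1)
                g_i = np.clip(grid[cells] + rng.uniform(-half_cell, half_cell, M),
                              window[0], window[1])
                imp[f"ga[{d.index[i]}]"] = g_i
            if np.isnan(hi):
                mean = _curve(s_i, g_i - 39.0)
                imp[f"hc[{d.index[i]}]"] = _sample_mix(mean, rng)

    return PosteriorDraws(
        params=draws,
        model="bsnmn",
        imputed_expl=_empty_imp(M),
        imputed_source=pd.DataFrame(imp) if imp else _empty_imp(M),
        diagnostics=diag,
    )


def logsumexp_lastaxis(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=-1, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=-1, keepdims=True)))[..., 0]


def sample_bsnmn_sources(
    params: Mapping,
    S: int,
    rng: np.random.Generator,
    sex=None,
    window=GA_WINDOW,
) -> pd.DataFrame:
    """Forward-simulate S rows of (sex, ga, hc) from BsNmN parameters.

    Gestational age is drawn from the skew-Normal by rejection into the
    validity window; ``sex`` optionally conditions the sex column.
    """
    mu, sg, om = params["mu"], params["sigma"], params["omega"]
    loc = 39.0 + skewnorm_location(mu, sg, om)
    if sex is None:
        sx = (rng.random(S) < 0.5).astype(float)
    else:
        sx = np.full(S, float(sex))
    ga = np.empty(0)
    while len(ga) < S:
        cand = stats.skewnorm.rvs(om, loc=loc, scale=sg, size=2 * S, random_state=rng)
        ga = np.concatenate([ga, cand[(cand >= window[0]) & (cand <= window[1])]])
    ga = ga[:S]
    dd = ga - 39.0
    curve = params["beta0"] + params["beta1"] * sx + params["beta2"] * dd + params["beta3"] * dd**2
    affected = rng.random(S) >= params["q"]
    sd = np.where(affected, params["zeta2"], params["zeta1"])
    shift = np.where(affected, params["kappa"], 0.0)
    hc = curve + shift + sd * rng.standard_normal(S)
    return pd.DataFrame({"sex": sx, "ga": ga, "hc": hc})


# ---------------------------------------------------------------------------
# implied prior on E(Y)
# ---------------------------------------------------------------------------


def _draw_bsnmn_prior(rng: np.random.Generator, priors: Mapping | None = None) -> dict:
    p = {**BSNMN_PRIOR, **(priors or {})}
    kmean, ksd, kup = p["kappa"]
    kappa = np.inf
    while kappa > kup:
        kappa = rng.normal(kmean, ksd)
    return {
        "mu": rng.normal(*p["mu"]),
        "sigma": stats.invgamma.rvs(p["sigma"][0], scale=p["sigma"][1], random_state=rng),
        "omega": rng.normal(*p["omega"]),
        "beta0": rng.normal(*p["beta0"]),
        "beta1": rng.normal(*p["beta1"]),
        "beta2": rng.normal(*p["beta2"]),
        "beta3": rng.normal(*p["beta3"]),
        "zeta1": stats.invgamma.rvs(p["zeta1"][0], scale=p["zeta1"][1], random_state=rng),
        "zeta2": stats.invgamma.rvs(p["zeta2"][0], scale=p["zeta2"][1], random_state=rng),
        "kappa": kappa,
        "q": rng.uniform(*p["q"]),
    }


def implied_prior_outcome(
    model_id: str,
    priors: Mapping | None = None,
    n_draws: int = 1000,
    S: int = 1000,
    seed: int = 0,
    ref: HCReference | None = None,
    spec=None,
) -> np.ndarray:
    """Sample the prior-implied distribution of E(Y) for a model.

    Each value is obtained by drawing parameters from the prior and Monte Carlo
    averaging the derived outcome over ``S`` forward-simulated source rows.
    For the conjugate Bernoulli model E(Y) = θ and the Beta prior is sampled
    directly.
    """
    rng = np.random.default_rng(seed)
    if model_id == "bernoulli":
        a, b = (priors or {}).get("theta", (1.26, 2.32))
        return rng.beta(a, b, size=n_draws)
    if model_id == "bsnmn":
        from .derive import microcephaly  # local to avoid cycle at import time

        r = ref if ref is not None else HCReference()
        out = np.empty(n_draws)
        for i in range(n_draws):
            psi = _draw_bsnmn_prior(rng, priors)
            src = sample_bsnmn_sources(psi, S, rng)
            out[i] = microcephaly(src["sex"], src["ga"], src["hc"], ref=r).mean()
        return out
    raise ValueError(f"model {model_id!r} does not support prior simulation")
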
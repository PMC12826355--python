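"""Comparator methods: chained-equations multiple imputation and posterior pooling.

Imputation is *proper* throughout: each conditional model first draws its
parameters from (an approximation of) their posterior and then draws the
missing values from the resulting predictive distribution.  Continuous
variables use Bayesian linear regression with the noninformative conjugate
draw (σ² from the scaled inverse-χ², coefficients from their conditional
Normal); binary variables use a logistic fit with an asymptotic-Normal
parameter draw, falling back to an L2-penalized fit under separation.

Source variables are imputed at the source level and the derived outcome is
recomputed from the current source values after every update — the
"on-the-fly" (passive) scheme — so every completed dataset satisfies the
deterministic source/outcome relationship exactly.  The pooled-posterior
("three-step") procedure then fits the analysis model once per completed
dataset and mixes all draws; no combining rules are applied.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import DerivedOutcomeSpec, MissingTable, PosteriorDraws

__all__ = ["ImputationConfig", "chained_impute", "gelman_three_step"]


@dataclass(frozen=True)
class ImputationConfig:
    """Settings for chained-equations imputation.

    ``methods`` maps each variable with missingness to ``"bayes-linear"`` or
    ``"bayes-logistic"``; K completed datasets are produced with ``cycles``
    full passes each.
    """

    K: int = 50
    cycles: int = 10
    methods: Mapping[str, str] = field(default_factory=dict)
    #: optional per-variable (lo, hi) bounds; predictive draws are squeezed into
    #: them (needed when the derivation has a validity window, e.g. gestational age)
    bounds: Mapping[str, tuple] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.cycles < 1:
            raise ValueError("K and cycles must be >= 1")
        bad = set(self.methods.values()) - {"bayes-linear", "bayes-logistic"}
        if bad:
            raise ValueError(f"unknown imputation methods: {sorted(bad)}")


def _mvn_draw(rng, mean, cov):
    """Multivariate-normal draw tolerant of nearly singular covariances
    (exact collinearity arises when the derived outcome sits in the
    predictor set together with its sources)."""
    cov = 0.5 * (cov + cov.T)
    try:
        return rng.multivariate_normal(mean, cov, method="cholesky")
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        w = np.clip(w, 0.0, None)
        return mean + (v * np.sqrt(w)) @ rng.standard_normal(len(mean))


def _draw_linear(X, y, Xmis, rng):
    """Posterior-predictive draw for a Normal linear conditional (Jeffreys prior)."""
    n, p = X.shape
    ridge = 1e-8 * (np.trace(X.T @ X) / p + 1.0)
    XtX = X.T @ X + ridge * np.eye(p)
    coef = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ coef
    dof = max(n - p, 2)
    s2 = float(resid @ resid) / dof
    sigma2 = s2 * dof / rng.chisquare(dof)
    cov = sigma2 * np.linalg.inv(XtX)
    beta = _mvn_draw(rng, coef, cov)
    return Xmis @ beta + np.sqrt(sigma2) * rng.standard_normal(len(Xmis))


def _draw_logistic(X, y, Xmis, rng):
    """Posterior-predictive Bernoulli draw via ML fit + asymptotic-Normal parameters."""
    beta_hat = cov = None
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            c = np.asarray(fit.cov_params())
            if (np.all(np.isfinite(fit.bse)) and np.max(np.abs(fit.params)) < 25
                    and np.all(np.isfinite(c))
                    and np.linalg.eigvalsh(0.5 * (c + c.T)).min() > 1e-12):
                beta_hat, cov = fit.params, c
        except Exception:
            pass
        if beta_hat is None:
            # fallback under separation or collinear predictors:
            # ridge-penalized fit, covariance from the penalized Hessian
            _warnings.warn(
                "logistic imputation hit separation/collinearity; using penalized draw",
                UserWarning, stacklevel=2)
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
                alpha=1.0, L1_wt=0.0)
            beta_hat = np.asarray(fit.params)
            eta = X @ beta_hat
            w = _expit(eta) * (1 - _expit(eta))
            H = (X * w[:, None]).T @ X + np.eye(X.shape[1])
            cov = np.linalg.inv(H)
    beta = _mvn_draw(rng, np.asarray(beta_hat), np.asarray(cov))
    p = _expit(Xmis @ beta)
    return (rng.random(len(Xmis)) < p).astype(float)


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def _default_methods(table: MissingTable) -> dict[str, str]:
    out = {}
    for c in table.data.columns:
        if table.roles[c] == "derived" or not table.mask[c].any():
            continue
        out[c] = "bayes-logistic" if c in table.binary else "bayes-linear"
    return out


def chained_impute(
    table: MissingTable,
    cfg: ImputationConfig,
    spec: DerivedOutcomeSpec,
) -> list[MissingTable]:
    """K completed datasets by chained equations with on-the-fly derivation.

    Predictors for a source variable are the other sources and the explanatory
    variables; predictors for an explanatory variable additionally include the
    freshly recomputed derived outcome.  With no missingness the input is
    returned K times unchanged.
    """
    methods = dict(_default_methods(table))
    methods.update(cfg.methods)
    y_col = table.derived_name
    mask = table.mask
    for v in methods:
        if v not in table.data.columns:
            raise ValueError(f"method declared for unknown variable {v!r}")
    undeclared = [c for c in table.data.columns
                  if c != y_col and mask[c].any() and c not in methods]
    if undeclared:
        raise ValueError(f"variables with missingness lack a method: {undeclared}")
    order = [c for c in table.data.columns if c in methods and mask[c].any()]

    def _recompute_derived(df):
        if y_col is not None:
            df[y_col] = spec.apply(df[list(spec.source_names)])

    rng_master = np.random.SeedSequence(cfg.seed)
    completed = []
    for k, ss in enumerate(rng_master.spawn(cfg.K)):
        rng = np.random.default_rng(ss)
        df = table.data.copy()
        # initialize each missing entry from its observed marginal
        for c in order:
            obs = df[c].dropna().to_numpy(float)
            df.loc[mask[c], c] = rng.choice(obs, size=int(mask[c].sum()), replace=True)
        _recompute_derived(df)
        for _ in range(cfg.cycles):
            for c in order:
                role = table.roles[c]
                preds = [v for v in df.columns
                         if v != c and (v != y_col or role == "explanatory")]
                X = np.column_stack([np.ones(len(df))]
                                    + [df[v].to_numpy(float) for v in preds])
                obs_rows = ~mask[c].to_numpy()
                mis_rows = mask[c].to_numpy()
                yv = df.loc[obs_rows, c].to_numpy(float)
                if methods[c] == "bayes-logistic":
                    draw = _draw_logistic(X[obs_rows], yv, X[mis_rows], rng)
                else:
                    draw = _draw_linear(X[obs_rows], yv, X[mis_rows], rng)
                if c in cfg.bounds:
                    draw = np.clip(draw, *cfg.bounds[c])
                df.loc[mis_rows, c] = draw
                if role == "source":
                    _recompute_derived(df)
        _recompute_derived(df)
        completed.append(MissingTable(data=df, roles=dict(table.roles),
                                      binary=table.binary))
    return completed


def gelman_three_step(
    completed: Sequence[MissingTable],
    fitter: Callable[..., PosteriorDraws],
    M: int = 2000,
    seed: int = 0,
) -> PosteriorDraws:
    """Fit the analysis model on each completed dataset and pool all draws.

    Returns K·M mixed draws with a ``dataset`` index column; per-dataset
    summaries are kept in the diagnostics.  Datasets whose fit fails the
    convergence gate are excluded with a warning; if more than half fail the
    pooling is abandoned.
    """
    K = len(completed)
    if K < 1:
        raise ValueError("need at least one completed dataset")
    pooled, per_dataset, failed = [], [], []
    for k, tab in enumerate(completed):
        fit = fitter(tab, M=M, seed=seed + k)
        if any("convergence" in w for w in fit.diagnostics.get("warnings", [])):
            failed.append(k)
            _warnings.warn(f"dataset {k} failed convergence; excluded from pooling",
                           UserWarning, stacklevel=2)
            continue
        frame = fit.params.copy()
        frame.insert(0, "dataset", k)
        pooled.append(frame)
        per_dataset.append(fit.params.median().to_dict())
    if len(failed) > K / 2:
        raise RuntimeError(f"{len(failed)} of {K} per-dataset fits failed convergence")
    params = pd.concat(pooled, ignore_index=True)
    diag = {"per_dataset_median": per_dataset, "failed": failed,
            "K": K, "warnings": []}
    return PosteriorDraws(params=params, model="pooled", diagnostics=diag)
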
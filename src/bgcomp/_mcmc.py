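"""Ensemble-MCMC backend shared by all model fits.

Parameters are sampled on an unconstrained scale (log / tanh / logit / shifted
transforms with their Jacobians) with an affine-invariant ensemble sampler and
a warmup phase; walkers are treated as chains for split-R̂ and bulk-ESS
diagnostics.  Convergence failures are recorded as warnings in the returned
diagnostics, never silently ignored.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import emcee
import numpy as np
import pandas as pd

with _warnings.catch_warnings():
    _warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

__all__ = [
    "Transform",
    "IDENTITY",
    "LOG",
    "TANH",
    "LOGIT",
    "upper_shift",
    "Param",
    "run_ensemble",
    "RHAT_GATE",
    "ESS_GATE",
]

RHAT_GATE = 1.05
ESS_GATE = 400.0


@dataclass(frozen=True)
class Transform:
    """Bijection from the unconstrained line to a parameter's support."""

    name: str
    constrain: Callable[[np.ndarray], np.ndarray]
    unconstrain: Callable[[np.ndarray], np.ndarray]
    log_jac: Callable[[np.ndarray], np.ndarray]  # log |d constrain / du|


IDENTITY = Transform("identity", lambda u: u, lambda x: x, lambda u: np.zeros_like(u))
LOG = Transform("log", np.exp, np.log, lambda u: u)  # x = e^u > 0
TANH = Transform(  # x in (-1, 1)
    "tanh",
    np.tanh,
    np.arctanh,
    lambda u: np.log1p(-np.tanh(u) ** 2 + 1e-300),
)


def _expit(u):
    return 0.5 * (1.0 + np.tanh(0.5 * u))


LOGIT = Transform(  # x in (0, 1)
    "logit",
    _expit,
    lambda x: np.log(x) - np.log1p(-x),
    lambda u: np.log(_expit(u) * (1.0 - _expit(u)) + 1e-300),
)


def upper_shift(c: float) -> Transform:
    """x = c − e^u, i.e. x < c (used for the upper-truncated shift κ < −1)."""
    return Transform(
        f"upper<{c}", lambda u: c - np.exp(u), lambda x: np.log(c - x), lambda u: u
    )


@dataclass(frozen=True)
class Param:
    """A named parameter with its support transform and prior log-density.

    ``log_prior`` is evaluated on the constrained scale and must be vectorized.
    ``init`` draws constrained starting values for the walkers.
    """

    name: str
    transform: Transform
    log_prior: Callable[[np.ndarray], np.ndarray]
    init: Callable[[np.random.Generator, int], np.ndarray]


def run_ensemble(
    params: Sequence[Param],
    log_lik: Callable[[pd.DataFrame], np.ndarray],
    M: int,
    seed: int,
    warmup: int = 1000,
    nwalkers: int | None = None,
    keep_steps: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw M post-warmup joint samples from prior × likelihood.

    ``log_lik`` receives a (K, ndim) DataFrame of constrained walker positions
    (columns named after the parameters) and returns K log-likelihoods; it is
    called in vectorized form.  The ensemble uses differential-evolution moves
    (with an occasional snooker move), which mix markedly faster than the
    stretch move on correlated posteriors; ``keep_steps`` post-warmup steps per
    walker are retained and evenly thinned down to M draws.  Returns an
    (M, ndim) frame of constrained draws and a diagnostics dict with
    per-parameter ``rhat``/``ess`` and any convergence ``warnings``.
    """
    params = list(params)
    ndim = len(params)
    names = [p.name for p in params]
    if nwalkers is None:
        nwalkers = max(2 * ndim + 2, 20)
    if nwalkers % 2:
        nwalkers += 1
    rng = np.random.default_rng(seed)

    def constrain(u: np.ndarray) -> np.ndarray:
        x = np.empty_like(u)
        for j, p in enumerate(params):
            x[..., j] = p.transform.constrain(u[..., j])
        return x

    def log_post(u: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(u)
        x = constrain(u)
        lp = np.zeros(len(u))
        for j, p in enumerate(params):
            lp += np.asarray(p.log_prior(x[:, j])) + p.transform.log_jac(u[:, j])
        ok = np.isfinite(lp)
        if ok.any():
            ll = np.asarray(log_lik(pd.DataFrame(x[ok], columns=names)))
            lp[ok] = lp[ok] + ll
        lp[~np.isfinite(lp)] = -np.inf
        return lp

    # constrained init draws -> unconstrained walker positions
    u0 = np.empty((nwalkers, ndim))
    for j, p in enumerate(params):
        x0 = np.asarray(p.init(rng, nwalkers), dtype=float)
        u0[:, j] = p.transform.unconstrain(x0)

    # post-warmup steps per walker; at least enough rows to thin down to M
    steps_keep = max(int(np.ceil(M / nwalkers)), 50, keep_steps or 0)
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_post, vectorize=True, moves=moves)
    sampler._random = np.random.mtrand.RandomState(rng.integers(2**31 - 1))
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        sampler.run_mcmc(u0, warmup + steps_keep, progress=False)

    chain_u = sampler.get_chain(discard=warmup)  # (steps, walkers, ndim)
    chain = constrain(chain_u)
    post = np.swapaxes(chain, 0, 1)  # (walkers, steps, ndim)

    diagnostics: dict = {"rhat": {}, "ess": {}, "warnings": [], "accept_frac": float(
        np.mean(sampler.acceptance_fraction)
    )}
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        for j, name in enumerate(names):
            arr = post[:, :, j]
            if np.allclose(arr.std(), 0.0):
                rhat, ess = 1.0, float(arr.size)
            else:
                ds = az.convert_to_dataset(arr)
                rhat = float(az.rhat(ds)["x"])
                ess = float(az.ess(ds)["x"])
            diagnostics["rhat"][name] = rhat
            diagnostics["ess"][name] = ess
    max_rhat = max(diagnostics["rhat"].values())
    min_ess = min(diagnostics["ess"].values())
    if max_rhat > RHAT_GATE:
        msg = f"convergence warning: max R-hat {max_rhat:.3f} > {RHAT_GATE}"
        diagnostics["warnings"].append(msg)
        _warnings.warn(msg, UserWarning, stacklevel=2)
    if min_ess < ESS_GATE:
        msg = f"convergence warning: min bulk ESS {min_ess:.0f} < {ESS_GATE:.0f}"
        diagnostics["warnings"].append(msg)

    # evenly thin the flattened post-warmup sample down to M draws
    flat = chain.reshape(-1, ndim)
    idx = np.linspace(0, len(flat) - 1, M).round().astype(int)
    draws = pd.DataFrame(flat[idx], columns=names)
    return draws, diagnostics
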
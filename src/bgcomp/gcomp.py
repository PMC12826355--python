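"""Bayesian g-computation: turning posterior parameter draws into estimand draws.

For each posterior draw m and each target population d, a large number S of
source-variable rows is forward-simulated from the fitted generative model,
the deterministic derivation f is applied to every row, and the sample mean
approximates the conditional expectation E*_d(E(Y|W_expl)).  Combining the D
expectations per the estimand definition yields one θ draw per posterior draw,
so parameter uncertainty, imputation uncertainty and the inner Monte Carlo
error all propagate into the posterior of θ.

Also provided: the ε-matching conditional-risk propagation, which restricts
the per-draw source banks to rows compatible with an individual's observed
source values and averages f over the G_m matches.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    DerivedOutcomeSpec,
    EstimandDraws,
    EstimandSpec,
    MissingTable,
    PopulationSpec,
    PosteriorDraws,
)
from .models import sample_bsnmn_sources, sample_growth_sources, sample_toy_sources

__all__ = [
    "register_simulator",
    "sample_sources",
    "draw_population_params",
    "expected_outcome",
    "gcompute",
    "make_source_bank",
    "conditional_outcome_prob",
    "ConditionalRisk",
]


# ---------------------------------------------------------------------------
# forward-simulator registry
# ---------------------------------------------------------------------------

_SIMULATORS: dict[str, Callable] = {}


def register_simulator(model: str, fn: Callable) -> None:
    """Register ``fn(params, pop, S, rng, table) -> DataFrame`` for a model family."""
    _SIMULATORS[model] = fn


def _empirical_covariate(table: MissingTable, name: str, S: int, rng) -> np.ndarray:
    vals = table.data[name].dropna().to_numpy(float)
    if len(vals) == 0:
        raise ValueError(f"no observed values of covariate {name!r} to resample")
    return rng.choice(vals, size=S, replace=True)


def _covariates(pop: PopulationSpec, name: str, S: int, rng, table) -> np.ndarray:
    if name in pop.conditioning:
        return np.full(S, float(pop.conditioning[name]))
    law = pop.covariate_law
    if callable(law):
        drawn = law(rng, S)
        return np.asarray(drawn[name] if isinstance(drawn, (pd.DataFrame, dict)) else drawn,
                          dtype=float)
    if law == "empirical":
        # plug-in: uniform resampling of the observed covariate rows
        if table is None:
            raise ValueError("empirical covariate law requires the observed table")
        return _empirical_covariate(table, name, S, rng)
    if law == "bayesian-bootstrap":
        # Dirichlet-weighted resampling: propagates uncertainty about the
        # covariate distribution itself (off by default)
        if table is None:
            raise ValueError("bayesian-bootstrap covariate law requires the observed table")
        vals = table.data[name].dropna().to_numpy(float)
        w = rng.dirichlet(np.ones(len(vals)))
        return rng.choice(vals, size=S, replace=True, p=w)
    raise ValueError(f"unknown covariate law {law!r}")


def _sim_toy(params, pop, S, rng, table):
    x = pop.conditioning.get("X")
    return sample_toy_sources(params, S, rng, x=x)


def _sim_bivariate(params, pop, S, rng, table):
    if "X" not in pop.conditioning:
        raise ValueError("the growth-model population must condition on the group X")
    ages = _covariates(pop, "A", S, rng, table)
    return sample_growth_sources(params, S, rng, x=pop.conditioning["X"], ages=ages)


def _sim_bsnmn(params, pop, S, rng, table):
    return sample_bsnmn_sources(params, S, rng, sex=pop.conditioning.get("sex"))


register_simulator("toy", _sim_toy)
register_simulator("bivariate", _sim_bivariate)
register_simulator("bsnmn", _sim_bsnmn)


# ---------------------------------------------------------------------------
# the §-by-step engine
# ---------------------------------------------------------------------------


def draw_population_params(
    draws: PosteriorDraws,
    pop: PopulationSpec,
    m: int,
    rng: np.random.Generator,
    table: MissingTable | None = None,
) -> dict[str, float]:
    """One draw of each unknown population parameter γ_d given the m-th record.

    Each entry of ``pop.gamma_spec`` is ``name -> fn(record, table, rng)`` where
    ``record`` is the m-th joint parameter/imputation record.  Returns an empty
    record when no γ_d is declared.
    """
    if not pop.gamma_spec:
        return {}
    record = draws.record(m)
    for frame in (draws.imputed_expl, draws.imputed_source):
        if len(frame):
            record.update({k: float(v) for k, v in frame.iloc[m].items()})
    out = {}
    for name, fn in pop.gamma_spec.items():
        try:
            out[name] = float(fn(record, table, rng))
        except KeyError as e:
            raise ValueError(f"gamma_spec {name!r} references unknown quantity {e}") from e
    return out


def sample_sources(
    model: str,
    params: Mapping,
    gamma: Mapping,
    pop: PopulationSpec,
    S: int,
    rng: np.random.Generator,
    table: MissingTable | None = None,
) -> pd.DataFrame:
    """Draw S iid source rows from the model's conditional law for population d."""
    if model not in _SIMULATORS:
        raise ValueError(f"no forward simulator registered for model {model!r}")
    merged = dict(params)
    merged.update(gamma or {})
    return _SIMULATORS[model](merged, pop, S, rng, table)


def expected_outcome(
    source_samples: pd.DataFrame, spec: DerivedOutcomeSpec
) -> tuple[float, float]:
    """Mean of f over the sampled rows, with the inner MC standard error sd/√S."""
    y = spec.apply(source_samples)
    S = len(y)
    if S < 1:
        raise ValueError("expected_outcome requires S >= 1 rows")
    return float(np.mean(y)), float(np.std(y, ddof=1) / np.sqrt(S)) if S > 1 else np.nan


def gcompute(
    draws: PosteriorDraws,
    populations: Sequence[PopulationSpec],
    estimand: EstimandSpec,
    spec: DerivedOutcomeSpec,
    S: int = 2000,
    seed: int = 0,
    table: MissingTable | None = None,
) -> EstimandDraws:
    """Monte Carlo g-computation: M posterior draws of θ through f.

    For each of the M parameter records, draws any unknown population
    parameters, forward-simulates S source rows per population, averages f, and
    combines the D expectations into θ[m].  A master seed derives independent
    per-draw substreams, so results are reproducible and the loop could be
    parallelized.  ``mc_se`` reports the largest per-draw combined inner Monte
    Carlo standard error.
    """
    if S < 1 or draws.M < 1:
        raise ValueError("S and M must be >= 1")
    M = draws.M
    streams = np.random.SeedSequence(seed).spawn(M)
    theta = np.empty(M)
    worst = 0.0
    for m in range(M):
        rng = np.random.default_rng(streams[m])
        record = draws.record(m)
        e = np.empty(len(populations))
        se2 = 0.0
        for j, pop in enumerate(populations):
            gamma = draw_population_params(draws, pop, m, rng, table)
            samples = sample_sources(draws.model, record, gamma, pop, S, rng, table)
            e[j], se = expected_outcome(samples, spec)
            if np.isfinite(se):
                se2 += se**2
        theta[m] = estimand.combine(e)
        worst = max(worst, np.sqrt(se2))
    return EstimandDraws(theta=theta, S=S, mc_se=worst)


# ---------------------------------------------------------------------------
# ε-matching conditional risk (downstream propagation)
# ---------------------------------------------------------------------------


def make_source_bank(
    draws: PosteriorDraws,
    pop: PopulationSpec,
    S: int,
    seed: int = 0,
    table: MissingTable | None = None,
) -> list[pd.DataFrame]:
    """The per-draw S×p source banks of g-computation step 2(a)ii, kept whole."""
    streams = np.random.SeedSequence(seed).spawn(draws.M)
    return [
        sample_sources(draws.model, draws.record(m), {}, pop, S,
                       np.random.default_rng(streams[m]), table)
        for m in range(draws.M)
    ]


@dataclass
class ConditionalRisk:
    """Per-draw conditional outcome probabilities from ε-matched source banks."""

    p_hat: np.ndarray            # (M,), NaN where no match was found
    G: np.ndarray                # (M,) match counts
    min_matches: int
    flagged: np.ndarray = field(default=None)  # draws with G < min_matches

    def __post_init__(self) -> None:
        if self.flagged is None:
            self.flagged = self.G < self.min_matches

    def summary(self) -> dict:
        ok = ~np.isnan(self.p_hat)
        lo, med, hi = np.percentile(self.p_hat[ok], [2.5, 50, 97.5])
        return {
            "median": float(med), "ci_low": float(lo), "ci_high": float(hi),
            "min_G": int(self.G.min()), "n_flagged": int(self.flagged.sum()),
        }


def conditional_outcome_prob(
    draws: PosteriorDraws,
    source_bank: Sequence[pd.DataFrame],
    condition: Mapping[str, float],
    tolerance: Mapping[str, float],
    spec: DerivedOutcomeSpec,
    min_matches: int = 50,
) -> ConditionalRisk:
    """Pr(Y=1 | observed source values) per posterior draw, by ε-matching.

    ``condition`` maps observed source names to their values; continuous
    conditions match within ±ε from ``tolerance`` (e.g. 0.25 cm for head
    circumference), others match exactly.  For each draw the bank is
    restricted to matching rows (G_m of them), the conditioned columns are
    pinned to their exact observed values, and f is averaged over the G_m
    completed rows.  Draws with G_m below ``min_matches`` are flagged; a draw
    with no match yields NaN with guidance to raise S or ε.
    """
    unknown = set(condition) - set(spec.source_names)
    if unknown:
        raise ValueError(f"condition names not among the sources: {sorted(unknown)}")
    if len(condition) >= len(spec.source_names):
        raise ValueError("at least one source variable must be left unconditioned")
    M = len(source_bank)
    p_hat = np.full(M, np.nan)
    G = np.zeros(M, dtype=int)
    for m, bank in enumerate(source_bank):
        keep = np.ones(len(bank), dtype=bool)
        for name, val in condition.items():
            col = bank[name].to_numpy(float)
            eps = tolerance.get(name)
            keep &= (np.abs(col - val) <= eps) if eps is not None else (col == val)
        G[m] = int(keep.sum())
        if G[m] == 0:
            continue
        rows = bank.loc[keep, list(spec.source_names)].copy()
        for name, val in condition.items():
            rows[name] = val
        p_hat[m] = float(np.mean(spec.apply(rows)))
    n_empty = int(np.isnan(p_hat).sum())
    if n_empty:
        _warnings.warn(
            f"{n_empty} of {M} draws had no ε-match (G_m = 0); "
            "increase S or the matching tolerance ε",
            UserWarning, stacklevel=2,
        )
    return ConditionalRisk(p_hat=p_hat, G=G, min_matches=min_matches)
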
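"""Synthetic study generators with configurable missingness mechanisms.

Three emulated studies:

* ``gen_toy`` — two groups, bivariate-Normal sources, Y = Z1 + Z2;
* ``gen_dutch_boys`` — a growth study of boys aged 1–18 with correlated
  log-height/log-weight, logBMI outcome and a small amount of missingness;
* ``gen_microcephaly`` — newborn sex / gestational age / head circumference
  from the BsNmN law with pattern-dependent missingness: sex missing
  completely at random, gestational age more often missing for very small
  head circumferences, head circumference more often missing at higher
  gestational ages.

The generators emulate the published study facts (fractions of complete rows,
generating risk level, direction of complete-case bias); they do not reproduce
any deposited dataset row-for-row.  Each generator returns the table together
with a sidecar dict of the generating truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import MissingTable
from .derive import HCReference, log_bmi, microcephaly, sum_outcome
from .models import (
    BivariateParams,
    BsNmNParams,
    ToyParams,
    sample_bsnmn_sources,
    sample_growth_sources,
    sample_toy_sources,
)

__all__ = [
    "LogisticModel",
    "MissingnessMechanism",
    "DUTCH_PATTERN_MECHANISM",
    "MICRO_MECHANISM",
    "gen_toy",
    "gen_dutch_boys",
    "gen_microcephaly",
    "true_theta",
    "toy_example_table",
]


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class LogisticModel:
    """Per-entry missingness probability expit(intercept + Σ coef·(value − center))."""

    intercept: float
    coefs: Mapping[str, float] = field(default_factory=dict)
    centers: Mapping[str, float] = field(default_factory=dict)

    def prob(self, values: pd.DataFrame) -> np.ndarray:
        lin = np.full(len(values), self.intercept, dtype=float)
        for name, c in self.coefs.items():
            lin += c * (values[name].to_numpy(float) - self.centers.get(name, 0.0))
        return _expit(lin)


@dataclass(frozen=True)
class MissingnessMechanism:
    """Independent per-variable logistic missingness models on the true values."""

    models: Mapping[str, LogisticModel]

    def sample_mask(self, values: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
        mask = pd.DataFrame(False, index=values.index, columns=values.columns)
        for name, model in self.models.items():
            mask[name] = rng.random(len(values)) < model.prob(values)
        return mask

    @staticmethod
    def mcar(names, p: float) -> "MissingnessMechanism":
        logit = np.log(p) - np.log1p(-p)
        return MissingnessMechanism({n: LogisticModel(float(logit)) for n in names})


#: dutch-boys pattern mechanism: height unmeasured for ~18/537 of boys, weight
#: additionally unmeasured for ~2/18 of those, city status missing for ~1/537 —
#: matching the observed per-variable counts and the ~19/537 incomplete rows.
DUTCH_PATTERN_MECHANISM = {
    "p_height": 18.0 / 537.0,
    "p_weight_given_height": 2.0 / 18.0,
    "p_x": 1.0 / 537.0,
}

#: microcephaly mechanism: sex MCAR; ga missing more often for small hc
#: (negative slope on centered hc); hc missing more often at high ga.
#: Slopes and intercepts calibrated (scripts/calibrate_missingness.py) so that
#: at the default truth ~1019/1800 rows are complete, the complete-case
#: estimate is biased low and SVL imputation is biased high.
MICRO_MECHANISM = MissingnessMechanism({
    "sex": LogisticModel(-2.1972),                                   # ≈ 10% MCAR
    "ga": LogisticModel(-1.76, {"hc": -0.40}, {"hc": 33.4}),
    "hc": LogisticModel(-1.76, {"ga": 0.80}, {"ga": 39.0}),
})


def _redraw_all_missing(values, mask, mechanism, key_cols, rng, max_tries=100):
    """Redraw mechanism rows until every row keeps at least one observed entry."""
    for _ in range(max_tries):
        bad = mask[key_cols].all(axis=1)
        if not bad.any():
            return mask
        sub = mechanism.sample_mask(values.loc[bad], rng)
        mask.loc[bad, sub.columns] = sub.to_numpy()
    # give up gracefully: reveal one random key column in the stragglers
    bad = mask[key_cols].all(axis=1)
    for i in values.index[bad]:
        mask.loc[i, rng.choice(key_cols)] = False
    return mask


def _apply_mask(df, mask):
    out = df.copy()
    out[mask.astype(bool)] = np.nan
    return out


# ---------------------------------------------------------------------------
# toy study
# ---------------------------------------------------------------------------


def gen_toy(
    n: int = 200,
    params: ToyParams = ToyParams(),
    mechanism: MissingnessMechanism | None = None,
    seed: int = 0,
    mcar_p: float = 0.1,
) -> tuple[MissingTable, dict]:
    """Two-group table with Y = Z1 + Z2; default mechanism is 10% MCAR per variable."""
    rng = np.random.default_rng(seed)
    src = sample_toy_sources(params.to_dict(), n, rng)
    df = pd.DataFrame({
        "X": src["X"].to_numpy(),
        "Y": np.nan,
        "Z1": src["Z1"].to_numpy(),
        "Z2": src["Z2"].to_numpy(),
    })
    if mechanism is None and mcar_p > 0:
        mechanism = MissingnessMechanism.mcar(("X", "Z1", "Z2"), mcar_p)
    if mechanism is not None:
        mask = mechanism.sample_mask(df[["X", "Z1", "Z2"]], rng)
        mask = _redraw_all_missing(df, mask, mechanism, ["X", "Z1", "Z2"], rng)
        df[["X", "Z1", "Z2"]] = _apply_mask(df[["X", "Z1", "Z2"]], mask)
    ok = df[["Z1", "Z2"]].notna().all(axis=1)
    df.loc[ok, "Y"] = sum_outcome(df.loc[ok, "Z1"], df.loc[ok, "Z2"])
    table = MissingTable(
        data=df,
        roles={"X": "explanatory", "Y": "derived", "Z1": "source", "Z2": "source"},
        binary=frozenset({"X"}),
    )
    truth = dict(params.to_dict())
    truth["theta"] = (params.muZ1B + params.muZ2B) - (params.muZ1A + params.muZ2A)
    return table, truth


def toy_example_table() -> MissingTable:
    """The eight-observation hypothetical table used in the worked example
    (groups coded X=0 for A, X=1 for B)."""
    df = pd.DataFrame(
        {
            "X": [0, 0, 0, 1, 1, 1, np.nan, 1],
            "Y": [np.nan, 1.59, np.nan, 2.40, 4.49, 3.52, 2.00, np.nan],
            "Z1": [np.nan, -0.09, 1.23, 2.20, 2.35, 0.49, -0.03, 1.01],
            "Z2": [1.71, 1.68, np.nan, 0.20, 2.14, 3.03, 2.03, np.nan],
        },
        index=range(1, 9),
    )
    return MissingTable(
        data=df,
        roles={"X": "explanatory", "Y": "derived", "Z1": "source", "Z2": "source"},
        binary=frozenset({"X"}),
    )


# ---------------------------------------------------------------------------
# growth study (boys aged 1-18)
# ---------------------------------------------------------------------------


def gen_dutch_boys(
    n: int = 537,
    params: BivariateParams = BivariateParams(),
    mechanism: Mapping | None = None,
    seed: int = 0,
    age_range: tuple[float, float] = (1.0, 18.0),
) -> tuple[MissingTable, dict]:
    """Growth-study table: ages uniform on [1, 18], ~9% city membership,
    correlated log-height/log-weight, logBMI derived.

    The default mechanism is the pattern mechanism calibrated to the study
    facts: in expectation 18 missing heights, 2 missing weights (always
    together with a missing height) and 1 missing city flag at n = 537,
    leaving ≈ 19 incomplete rows.
    """
    rng = np.random.default_rng(seed)
    ages = rng.uniform(age_range[0], age_range[1], n)
    x = (rng.random(n) < params.pi).astype(float)
    p = params.to_dict()
    # simulate per group to honour the conditional law
    grown = sample_growth_sources(p, n, rng, x=0.0, ages=ages)
    grown1 = sample_growth_sources(p, n, rng, x=1.0, ages=ages)
    height = np.where(x == 1, grown1["height"], grown["height"])
    weight = np.where(x == 1, grown1["weight"], grown["weight"])
    df = pd.DataFrame({"X": x, "A": ages, "height": height, "weight": weight,
                       "logBMI": np.nan})
    mech = dict(DUTCH_PATTERN_MECHANISM, **(mechanism or {}))
    m_h = rng.random(n) < mech["p_height"]
    m_w = m_h & (rng.random(n) < mech["p_weight_given_height"])
    m_x = rng.random(n) < mech["p_x"]
    df.loc[m_h, "height"] = np.nan
    df.loc[m_w, "weight"] = np.nan
    df.loc[m_x, "X"] = np.nan
    ok = df[["height", "weight"]].notna().all(axis=1)
    df.loc[ok, "logBMI"] = log_bmi(df.loc[ok, "height"], df.loc[ok, "weight"])
    table = MissingTable(
        data=df,
        roles={"X": "explanatory", "A": "explanatory", "height": "source",
               "weight": "source", "logBMI": "derived"},
        binary=frozenset({"X"}),
    )
    truth = dict(p)
    mean_age = 0.5 * (age_range[0] + age_range[1])
    truth["theta"] = (params.gamma1 - 2 * params.alpha1
                      + (params.gamma3 - 2 * params.alpha3) * mean_age)
    return table, truth


# ---------------------------------------------------------------------------
# microcephaly study
# ---------------------------------------------------------------------------


def gen_microcephaly(
    n: int = 1800,
    psi_true: BsNmNParams = BsNmNParams(),
    ref: HCReference = HCReference(),
    mechanism: MissingnessMechanism | None = MICRO_MECHANISM,
    seed: int = 0,
) -> tuple[MissingTable, dict]:
    """Newborn table of (sex, ga, hc) with derived microcephaly status.

    Rows that would lose all three source entries are redrawn, so every newborn
    has at least one observed measurement.  The default truth and mechanism are
    calibrated to a generating risk ≈ 11.7% with ≈ 1019/1800 complete rows and
    a complete-case subset depleted of affected newborns.
    """
    rng = np.random.default_rng(seed)
    src = sample_bsnmn_sources(psi_true.to_dict(), n, rng)
    df = pd.DataFrame({"sex": src["sex"], "ga": src["ga"], "hc": src["hc"],
                       "Y": np.nan})
    if mechanism is not None:
        cols = ["sex", "ga", "hc"]
        mask = mechanism.sample_mask(df[cols], rng)
        mask = _redraw_all_missing(df, mask, mechanism, cols, rng)
        df[cols] = _apply_mask(df[cols], mask)
    ok = df[["sex", "ga", "hc"]].notna().all(axis=1)
    df.loc[ok, "Y"] = microcephaly(df.loc[ok, "sex"], df.loc[ok, "ga"],
                                   df.loc[ok, "hc"], ref=ref)
    table = MissingTable(
        data=df,
        roles={"sex": "source", "ga": "source", "hc": "source", "Y": "derived"},
        binary=frozenset({"sex", "Y"}),
    )
    truth = dict(psi_true.to_dict())
    truth["ref"] = ref.to_dict()
    theta, _ = true_theta(psi_true, ref, S=200_000, seed=seed + 1)
    truth["theta"] = theta
    return table, truth


def true_theta(
    psi_true: BsNmNParams,
    ref: HCReference = HCReference(),
    S: int = 1_000_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte Carlo generating risk Pr(microcephaly) under a BsNmN truth, with MCSE."""
    if S < 1:
        raise ValueError("S must be >= 1")
    rng = np.random.default_rng(seed)
    src = sample_bsnmn_sources(psi_true.to_dict(), S, rng)
    y = microcephaly(src["sex"], src["ga"], src["hc"], ref=ref)
    p = float(np.mean(y))
    return p, float(np.sqrt(max(p * (1 - p), 1e-300) / S))
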
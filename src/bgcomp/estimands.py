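"""Closed-form estimand mappings, used as fast paths and as oracles for g-computation.

Each mapping is linear in the coefficient draws, so applying it to posterior
means equals the mean of the applied draws.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["h1", "h2", "toy_theta"]


def _col(draws, name) -> np.ndarray:
    frame = draws.params if hasattr(draws, "params") else draws
    return np.asarray(frame[name], dtype=float)


def h1(draws, mean_age: float) -> np.ndarray:
    """θ = β1 + β3·E(A) per draw, for the univariate outcome regression.

    ``mean_age`` stands in for E(A); with a representative sample the observed
    sample mean of age is the natural plug-in.
    """
    return _col(draws, "beta1") + _col(draws, "beta3") * mean_age


def h2(draws, mean_age: float) -> np.ndarray:
    """θ = γ1 − 2α1 + (γ3 − 2α3)·E(A) per draw, for the bivariate growth model.

    This is the analytic mean difference in logBMI between groups implied by the
    log-height/log-weight regressions (logBMI = log weight − 2·log height +
    const, so the group contrast of its conditional mean at age a is
    (γ1 − 2α1) + (γ3 − 2α3)·a, averaged over the age distribution).
    """
    return (
        _col(draws, "gamma1")
        - 2.0 * _col(draws, "alpha1")
        + (_col(draws, "gamma3") - 2.0 * _col(draws, "alpha3")) * mean_age
    )


def toy_theta(draws) -> np.ndarray:
    """θ = (μZ1,B + μZ2,B) − (μZ1,A + μZ2,A) per draw: E(Y|X=1) − E(Y|X=0)."""
    return (
        _col(draws, "muZ1B") + _col(draws, "muZ2B")
        - _col(draws, "muZ1A") - _col(draws, "muZ2A")
    )


def observed_mean_age(table, a_col: str = "A") -> float:
    """Sample mean of the (fully observed) age column, the default E(A) plug-in."""
    a = table.data[a_col]
    return float(a.mean())
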
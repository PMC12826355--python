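"""Deterministic derivation functions f(·) mapping source variables to outcomes.

Three derivations are provided: the toy sum outcome, logBMI from height and
weight, and newborn microcephaly status from sex, gestational age and head
circumference.  Microcephaly is defined against a parametric quadratic
reference curve for mean head circumference (:class:`HCReference`): a newborn
whose head-circumference z-score falls strictly below −2 is classified as
microcephalic, so in a healthy Gaussian population matching the reference one
expects Φ(−2) ≈ 2.28% of newborns to be classified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import DerivedOutcomeSpec

__all__ = [
    "HCReference",
    "sum_outcome",
    "log_bmi",
    "hc_zscore",
    "microcephaly",
    "GA_WINDOW",
    "toy_spec",
    "logbmi_spec",
    "microcephaly_spec",
]

#: gestational-age validity window in weeks (viability to induced-labour cutoff)
GA_WINDOW = (24.0, 45.0)


@dataclass(frozen=True)
class HCReference:
    """Quadratic reference curve for mean head circumference at birth (cm).

    mean(sex, ga) = b0 + b1·sex + b2·(ga − 39) + b3·(ga − 39)², with sex coded
    0 = male, 1 = female and gestational age in weeks.  ``ref_sd`` is the
    reference standard deviation used for z-scoring.  This is a parametric
    stand-in for tabulated newborn growth standards; the default coefficients
    describe a plausible term-newborn population and the method is agnostic to
    the particular reference used.
    """

    b0: float = 33.912
    b1: float = -0.450
    b2: float = 0.399
    b3: float = -0.016
    ref_sd: float = 1.3

    def __post_init__(self) -> None:
        if self.ref_sd <= 0:
            raise ValueError("ref_sd must be positive")

    def mean(self, sex, ga_weeks):
        d = np.asarray(ga_weeks, dtype=float) - 39.0
        return self.b0 + self.b1 * np.asarray(sex, dtype=float) + self.b2 * d + self.b3 * d**2

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("b0", "b1", "b2", "b3", "ref_sd")}


def sum_outcome(z1, z2):
    """Y = Z1 + Z2 (the toy derived outcome)."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    return z1 + z2


def log_bmi(height_cm, weight_kg):
    """log BMI = log( weight_kg / (height_cm/100)² ); inputs must be positive."""
    h = np.asarray(height_cm, dtype=float)
    w = np.asarray(weight_kg, dtype=float)
    if np.any(h <= 0) or np.any(w <= 0):
        raise ValueError("log_bmi requires strictly positive height and weight")
    return np.log(w / (h / 100.0) ** 2)


def _check_ga(ga, window):
    lo, hi = window
    ga = np.asarray(ga, dtype=float)
    if np.any(ga < lo) or np.any(ga > hi):
        raise ValueError(f"gestational age outside validity window [{lo}, {hi}] weeks")
    return ga


def hc_zscore(sex, ga_weeks, hc_cm, ref: HCReference = HCReference(), window=GA_WINDOW):
    """Head-circumference z-score: (hc − mean(sex, ga)) / ref_sd."""
    ga = _check_ga(ga_weeks, window)
    return (np.asarray(hc_cm, dtype=float) - ref.mean(sex, ga)) / ref.ref_sd


def microcephaly(sex, ga_weeks, hc_cm, ref: HCReference = HCReference(), window=GA_WINDOW):
    """Microcephaly indicator: 1 iff the z-score is strictly below −2."""
    z = hc_zscore(sex, ga_weeks, hc_cm, ref=ref, window=window)
    return (z < -2.0).astype(float)


# -- ready-made DerivedOutcomeSpec instances --------------------------------


def toy_spec() -> DerivedOutcomeSpec:
    """Y = Z1 + Z2 on source columns (Z1, Z2)."""
    return DerivedOutcomeSpec(sum_outcome, ("Z1", "Z2"), "continuous", name="Y")


def logbmi_spec() -> DerivedOutcomeSpec:
    """logBMI on source columns (height, weight)."""
    return DerivedOutcomeSpec(log_bmi, ("height", "weight"), "continuous", name="logBMI")


def microcephaly_spec(ref: HCReference | None = None) -> DerivedOutcomeSpec:
    """Microcephaly status on source columns (sex, ga, hc) under a reference curve."""
    r = ref if ref is not None else HCReference()
    return DerivedOutcomeSpec(
        lambda s, g, h: microcephaly(s, g, h, ref=r),
        ("sex", "ga", "hc"),
        "binary",
        name="Y",
    )
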
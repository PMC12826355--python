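"""Calibration helper for the newborn-study missingness mechanism.

Sweeps the gestational-age and head-circumference missingness intercepts and
reports the mean number of complete rows per 1800 newborns, so the shipped
defaults can be re-derived (target: ~1019/1800 complete with the declared
slopes).  Exploration tool; not part of the analysis pipeline.

Usage::

    python scripts/calibrate_missingness.py [--seeds 12]
"""

from __future__ import annotations

import argparse

import numpy as np

from bgcomp.datamodel import complete_cases
from bgcomp.synthetic import LogisticModel, MissingnessMechanism, gen_microcephaly


def mean_complete(ga_intercept, hc_intercept, seeds):
    mech = MissingnessMechanism({
        "sex": LogisticModel(-2.1972),
        "ga": LogisticModel(ga_intercept, {"hc": -0.50}, {"hc": 33.4}),
        "hc": LogisticModel(hc_intercept, {"ga": 0.25}, {"ga": 39.0}),
    })
    counts = [
        complete_cases(gen_microcephaly(n=1800, seed=s, mechanism=mech)[0]).n
        for s in range(seeds)
    ]
    return float(np.mean(counts))


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seeds", type=int, default=12)
    args = ap.parse_args()
    print(f"{'ga_icpt':>8} {'hc_icpt':>8} {'mean complete / 1800':>22}")
    for ga_i in (-1.45, -1.52, -1.57, -1.62):
        for hc_i in (-1.45, -1.50, -1.55, -1.60):
            m = mean_complete(ga_i, hc_i, args.seeds)
            print(f"{ga_i:8.2f} {hc_i:8.2f} {m:22.1f}")


if __name__ == "__main__":
    main()
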
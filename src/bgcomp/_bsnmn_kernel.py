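"""Compiled observed-data log-likelihood for the BsNmN source model.

The gestational-age law is a skew-Normal restricted to the validity window;
its truncation constant is obtained by trapezoid quadrature on the same grid
used to marginalize rows with a missing gestational age, so the likelihood is
self-consistent.  Sex codes: 0 / 1 observed, 2 missing (marginalized with
probability ½ each).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT2PI = math.sqrt(2.0 * math.pi)
_LOG_HALF = math.log(0.5)


@njit(cache=True)
def _log_norm_cdf(x: float) -> float:
    if x > -25.0:
        return math.log(0.5 * math.erfc(-x / math.sqrt(2.0)))
    # asymptotic tail to avoid erfc underflow
    return -0.5 * x * x - math.log(-x) - 0.5 * math.log(2.0 * math.pi)


@njit(cache=True)
def _npdf(x: float, m: float, sd: float) -> float:
    z = (x - m) / sd
    return math.exp(-0.5 * z * z) / (sd * _SQRT2PI)


@njit(cache=True)
def _mixpdf(h: float, m: float, kp: float, z1: float, z2: float, q: float) -> float:
    return q * _npdf(h, m, z1) + (1.0 - q) * _npdf(h, m + kp, z2)


@njit(cache=True)
def bsnmn_loglik(P, ga_obs, g2, h2, s2, h3, s3, n_sex_obs, grid, tw):
    """(K,) observed-data log-likelihood.

    P columns: mu, sigma, omega, beta0..beta3, zeta1, zeta2, kappa, q.
    ga_obs — all observed gestational ages; (g2, h2, s2) — rows with ga and hc
    observed; (h3, s3) — rows with ga missing and hc observed; grid/tw — the
    quadrature grid over the ga window and its trapezoid weights.
    """
    K = P.shape[0]
    G = grid.shape[0]
    out = np.empty(K)
    pdfg = np.empty(G)
    wj = np.empty(G)
    cj = np.empty(G)
    for k in range(K):
        mu = P[k, 0]; sg = P[k, 1]; om = P[k, 2]
        b0 = P[k, 3]; b1 = P[k, 4]; b2 = P[k, 5]; b3 = P[k, 6]
        z1 = P[k, 7]; z2 = P[k, 8]; kp = P[k, 9]; q = P[k, 10]
        delta = om / math.sqrt(1.0 + om * om)
        loc = 39.0 + mu - sg * delta * math.sqrt(2.0 / math.pi)
        norm = 0.0
        for j in range(G):
            t = (grid[j] - loc) / sg
            phi = math.exp(-0.5 * t * t) / _SQRT2PI
            cdf = 0.5 * math.erfc(-om * t / math.sqrt(2.0))
            pdfg[j] = 2.0 / sg * phi * cdf
            norm += tw[j] * pdfg[j]
            d = grid[j] - 39.0
            cj[j] = b0 + b2 * d + b3 * d * d
        if norm < 1e-300 or not math.isfinite(norm):
            out[k] = -np.inf
            continue
        lognorm = math.log(norm)
        for j in range(G):
            wj[j] = tw[j] * pdfg[j]
        ll = n_sex_obs * _LOG_HALF
        # observed gestational ages under the truncated skew-Normal
        for i in range(ga_obs.shape[0]):
            t = (ga_obs[i] - loc) / sg
            lp = (math.log(2.0) - math.log(sg) - 0.5 * t * t
                  - 0.5 * math.log(2.0 * math.pi) + _log_norm_cdf(om * t))
            ll += lp - lognorm
        # head circumference given observed gestational age
        for i in range(g2.shape[0]):
            d = g2[i] - 39.0
            base = b0 + b2 * d + b3 * d * d
            if s2[i] == 2.0:
                p = 0.5 * (_mixpdf(h2[i], base, kp, z1, z2, q)
                           + _mixpdf(h2[i], base + b1, kp, z1, z2, q))
            else:
                p = _mixpdf(h2[i], base + b1 * s2[i], kp, z1, z2, q)
            ll += math.log(max(p, 1e-300))
        # head circumference with gestational age marginalized by quadrature
        for i in range(h3.shape[0]):
            acc = 0.0
            if s3[i] == 2.0:
                for j in range(G):
                    acc += wj[j] * 0.5 * (
                        _mixpdf(h3[i], cj[j], kp, z1, z2, q)
                        + _mixpdf(h3[i], cj[j] + b1, kp, z1, z2, q))
            else:
                sv = s3[i]
                for j in range(G):
                    acc += wj[j] * _mixpdf(h3[i], cj[j] + b1 * sv, kp, z1, z2, q)
            ll += math.log(max(acc, 1e-300)) - lognorm
        out[k] = ll
    return out
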
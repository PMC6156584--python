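"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths of the package: the two-part LRT
oracle maximizes the full two-part likelihood numerically, and the
hypergeometric oracle enumerates the tail sum combinatorially.
"""
from __future__ import annotations

from math import comb

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit


def _two_part_negll(theta, groups, shared: bool):
    """Negative log-likelihood of the two-part model.

    ``groups`` is a list of 1-d arrays. Shared: (logit p, mu, log sigma) for
    all groups; otherwise per-group (logit p_g, mu_g) plus one shared
    log sigma at the end.
    """
    if shared:
        params = [(theta[0], theta[1])] * len(groups)
        log_sigma = theta[2]
    else:
        params = [(theta[2 * i], theta[2 * i + 1]) for i in range(len(groups))]
        log_sigma = theta[-1]
    sigma = np.exp(log_sigma)
    ll = 0.0
    for (lp, mu), x in zip(params, groups):
        p = expit(lp)
        k = int((x > 0).sum())
        n = x.size
        pos = x[x > 0]
        ll += k * np.log(max(p, 1e-300)) + (n - k) * np.log(max(1 - p, 1e-300))
        ll += -0.5 * np.sum(((pos - mu) / sigma) ** 2) \
            - pos.size * (np.log(sigma) + 0.5 * np.log(2 * np.pi))
    return -ll


def _maximize(groups, shared: bool) -> float:
    allpos = np.concatenate([x[x > 0] for x in groups])
    mu0, sd0 = float(allpos.mean()), float(max(allpos.std(), 1e-3))
    if shared:
        k = sum(int((x > 0).sum()) for x in groups)
        n = sum(x.size for x in groups)
        p0 = np.clip(k / n, 1e-3, 1 - 1e-3)
        x0 = [np.log(p0 / (1 - p0)), mu0, np.log(sd0)]
    else:
        x0 = []
        for x in groups:
            p0 = np.clip((x > 0).mean(), 1e-3, 1 - 1e-3)
            x0 += [np.log(p0 / (1 - p0)), float(x[x > 0].mean())]
        x0 += [np.log(sd0)]
    best = None
    for scale in (1.0, 0.5):
        res = minimize(_two_part_negll, np.asarray(x0) * scale,
                       args=(groups, shared), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 20000, "maxfev": 20000})
        if best is None or res.fun < best:
            best = res.fun
    return -best


def oracle_two_part_stat(a: np.ndarray, b: np.ndarray) -> float:
    """LRT statistic by numeric maximization of the two-part likelihood.

    Valid when both groups have >= 2 positive values (the regime where the
    continuous component is defined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ll_alt = _maximize([a, b], shared=False)
    ll_null = _maximize([a, b], shared=True)
    return max(0.0, 2.0 * (ll_alt - ll_null))


def oracle_hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """P(overlap >= k) for a draw of n from N with K marked, by enumeration."""
    total = comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += comb(K, j) * comb(N - K, n - j)
    return acc / total
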
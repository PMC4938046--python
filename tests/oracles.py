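"""Independent reference computations used to check the library's results.

These deliberately avoid the code paths they verify: the binomial oracle
enumerates the whole outcome space with exact rational arithmetic, the
interval oracle re-evaluates the Agresti-Coull formula from its definition,
and the mixed-logit oracle evaluates the marginal likelihood with plain
(non-adaptive) 64-node Gauss-Hermite quadrature on the standardised scale
and maximises it by Nelder-Mead.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, sqrt

import numpy as np
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import norm


def enumerate_binomial_two_sided(k: int, n: int, p0: Fraction) -> float:
    """Point-probability two-sided p-value by exhaustive enumeration.

    Sums P(X = x) over every outcome x whose exact probability is at most
    (1 + 1e-7) times that of the observed k, with pmf values computed as
    exact fractions so the inclusion rule has no rounding ambiguity.
    """
    p0 = Fraction(p0)
    pmf = [comb(n, x) * p0**x * (1 - p0) ** (n - x) for x in range(n + 1)]
    threshold = pmf[k] * (Fraction(10**7 + 1, 10**7))
    return float(sum(p for p in pmf if p <= threshold))


def agresti_coull_direct(k: int, n: int, confidence: float) -> tuple[float, float, float]:
    """(point, lower, upper) from a literal transcription of the formula."""
    z = norm.ppf(1.0 - (1.0 - confidence) / 2.0)
    n_tilde = n + z * z
    p_tilde = (k + z * z / 2.0) / n_tilde
    half = z * sqrt(p_tilde * (1.0 - p_tilde) / n_tilde)
    return p_tilde, max(0.0, p_tilde - half), min(1.0, p_tilde + half)


_NODES64, _WEIGHTS64 = np.polynomial.hermite.hermgauss(64)


def gh64_marginal_loglik(
    params: np.ndarray, y: np.ndarray, X: np.ndarray, groups: np.ndarray
) -> float:
    """Mixed-logit marginal log-likelihood via fixed 64-node Gauss-Hermite.

    Integrates over the standardised colony effect v ~ N(0, 1) with the
    physicists' rule, so the colony intercept is sigma * sqrt(2) * x_k at
    node x_k; no mode-finding or rescaling is involved.
    """
    beta, sigma = params[:-1], abs(params[-1])
    eta_fixed = X @ beta
    total = 0.0
    for g in np.unique(groups):
        mask = groups == g
        eta = eta_fixed[mask][:, None] + np.sqrt(2.0) * sigma * _NODES64[None, :]
        log_bern = np.sum(y[mask][:, None] * eta - np.logaddexp(0.0, eta), axis=0)
        total += logsumexp(np.log(_WEIGHTS64) + log_bern) - 0.5 * np.log(np.pi)
    return float(total)


def fit_glmm_by_nelder_mead(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, x0: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Direct maximisation of :func:`gh64_marginal_loglik`; (params, loglik)."""
    if x0 is None:
        x0 = np.append(np.zeros(X.shape[1]), 0.5)

    def nll(params):
        return -gh64_marginal_loglik(params, y, X, groups)

    res = optimize.minimize(
        nll,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 50000, "maxfev": 50000},
    )
    params = res.x.copy()
    params[-1] = abs(params[-1])
    return params, -float(res.fun)
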
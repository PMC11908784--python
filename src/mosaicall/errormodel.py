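"""Site-specific beta-binomial background error model.

The model describes the number of non-reference reads ``x`` out of ``n``
reads at one panel site as beta-binomial with mean error rate ``mu`` and
overdispersion ``rho`` in ``[0, 1)``.  The shape parameters are

    a = mu * (1/rho - 1),    b = (1 - mu) * (1/rho - 1)

so that ``rho -> 0`` recovers the plain binomial and ``rho`` directly
measures the between-sample variance inflation ``1 + (n - 1) * rho``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import betaln, gammaln

__all__ = [
    "MU_FLOOR",
    "RHO_FLOOR",
    "ErrorModelFit",
    "beta_binomial_loglik",
    "fit_beta_binomial",
    "rho_moment_estimate",
    "weighted_mu_estimate",
]

#: Lower bound for the error-rate estimate; also used as 1 - upper bound.
MU_FLOOR = 1e-8
#: Lower bound for the overdispersion estimate.
RHO_FLOOR = 1e-8
#: Upper bound for the overdispersion estimate.
RHO_CEIL = 1.0 - 1e-6
#: Below this value the beta-binomial is evaluated as a plain binomial
#: (the log-gamma identities lose precision for extreme shape parameters).
_RHO_BINOMIAL_SWITCH = 1e-8


class InvalidParameterError(ValueError):
    """Raised when a likelihood is requested outside the parameter domain."""


class DegenerateInputError(ValueError):
    """Raised when a fit is requested on data carrying no information."""


@dataclass(frozen=True)
class ErrorModelFit:
    """Maximum-likelihood background error model at one site."""

    mu: float
    rho: float
    loglik: float
    n_background: int
    converged: bool
    site_id: str | None = None
    alt: str | None = None


def _validate_counts(x, n) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(x < 0) or np.any(n < 0):
        raise InvalidParameterError("counts must be non-negative")
    if np.any(x > n):
        raise InvalidParameterError("alt count exceeds depth")
    return x, n


def beta_binomial_loglik(x, n, mu: float, rho: float):
    """Log pmf of the beta-binomial in the (mu, rho) parameterization.

    Accepts scalars or arrays for ``x`` and ``n`` (broadcast together).
    ``n == 0`` contributes 0 (the empty observation has probability one).
    """
    scalar = np.isscalar(x) and np.isscalar(n)
    x, n = _validate_counts(x, n)
    if not (0.0 < mu < 1.0):
        raise InvalidParameterError(f"mu={mu} outside (0, 1)")
    if not (0.0 <= rho < 1.0):
        raise InvalidParameterError(f"rho={rho} outside [0, 1)")
    x, n = np.broadcast_arrays(x, n)
    if rho <= _RHO_BINOMIAL_SWITCH:
        out = stats.binom.logpmf(x, n, mu)
    else:
        s = 1.0 / rho - 1.0
        a = mu * s
        b = (1.0 - mu) * s
        choose = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
        out = choose + betaln(x + a, n - x + b) - betaln(a, b)
    out = np.where(n == 0, 0.0, out)
    return float(out) if scalar else out


def _neg_loglik(params: np.ndarray, x: np.ndarray, n: np.ndarray) -> float:
    mu, rho = params
    mu = min(max(mu, MU_FLOOR), 1.0 - MU_FLOOR)
    rho = min(max(rho, RHO_FLOOR), RHO_CEIL)
    return -float(np.sum(beta_binomial_loglik(x, n, mu, rho)))


def rho_moment_estimate(x, n) -> float:
    """Moment estimate of the overdispersion across samples (Kleinman).

    Used both to initialize the maximum-likelihood fit and as the plug-in
    dispersion of the batched likelihood-ratio caller.
    """
    x, n = _validate_counts(x, n)
    pos = n > 0
    x, n = x[pos], n[pos]
    k = len(n)
    if k < 2:
        return RHO_FLOOR
    ntot = n.sum()
    p_hat = x.sum() / ntot
    if p_hat <= 0.0 or p_hat >= 1.0:
        return RHO_FLOOR
    p_i = x / n
    s = float(np.sum(n * (p_i - p_hat) ** 2))
    denom_df = ntot - np.sum(n**2) / ntot
    denom = denom_df - (k - 1)
    if denom <= 0:
        return RHO_FLOOR
    rho = (s / (p_hat * (1.0 - p_hat)) - (k - 1)) / denom
    return float(min(max(rho, RHO_FLOOR), RHO_CEIL))


def weighted_mu_estimate(x, n, rho: float) -> float:
    """Quasi-likelihood error-rate estimate with effective-depth weights.

    Each sample contributes ``n_i / (1 + (n_i - 1) * rho)`` effective reads,
    the inverse-variance weighting for a beta-binomial observation.
    """
    x, n = _validate_counts(x, n)
    w = 1.0 / (1.0 + np.maximum(n - 1.0, 0.0) * rho)
    denom = float(np.sum(n * w))
    if denom <= 0:
        return MU_FLOOR
    mu = float(np.sum(x * w)) / denom
    return min(max(mu, MU_FLOOR), 1.0 - MU_FLOOR)


def fit_beta_binomial(xs, ns, *, site_id: str | None = None, alt: str | None = None) -> ErrorModelFit:
    """Maximum-likelihood (mu, rho) across background samples at one site.

    Initialized by method of moments and refined with bounded L-BFGS-B.
    Deterministic for fixed inputs.  With no alt reads at all the MLE sits
    on the floor of both parameters and is returned directly.
    """
    xs, ns = _validate_counts(xs, ns)
    if len(xs) != len(ns):
        raise InvalidParameterError("xs and ns must have equal length")
    if len(xs) < 2:
        raise InvalidParameterError("need at least two background samples")
    if np.all(ns == 0):
        raise DegenerateInputError("all depths are zero")

    n_bg = int(len(xs))
    if xs.sum() == 0:
        ll = float(np.sum(beta_binomial_loglik(xs, ns, MU_FLOOR, RHO_FLOOR)))
        return ErrorModelFit(MU_FLOOR, RHO_FLOOR, ll, n_bg, True, site_id, alt)

    rho0 = rho_moment_estimate(xs, ns)
    mu0 = weighted_mu_estimate(xs, ns, rho0)
    res = optimize.minimize(
        _neg_loglik,
        x0=np.array([mu0, max(rho0, 1e-6)]),
        args=(xs, ns),
        method="L-BFGS-B",
        bounds=[(MU_FLOOR, 1.0 - MU_FLOOR), (RHO_FLOOR, RHO_CEIL)],
        options={"maxiter": 200},
    )
    mu, rho = res.x
    mu = float(min(max(mu, MU_FLOOR), 1.0 - MU_FLOOR))
    rho = float(min(max(rho, RHO_FLOOR), RHO_CEIL))
    return ErrorModelFit(mu, rho, -float(res.fun), n_bg, bool(res.success), site_id, alt)
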
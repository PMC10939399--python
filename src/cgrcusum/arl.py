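"""Fisher information of the observation process and approximate ARL solvers.

When subjects arrive by a Poisson process with rate ``psi`` and fail with
hazard ratio ``exp(theta)`` on a known null model, the information about
``theta`` accumulated by calendar time ``t`` is

    I(theta, t) = psi * int_0^t E_Z[ F^theta(s) ] ds,

with ``F^theta(s) = 1 - exp(-exp(theta) exp(Z'beta) H0(s))`` the failure CDF
of a random subject.  Equating the deterministic drift of a chart to its
control limit h yields an approximate out-of-control average run length:

* CGI/CGR: solve ``(theta + exp(-theta) - 1) I(theta, t) = h`` — an upper
  bound for the CGR ARL when the hazard is raised from the start.
* BK:      solve ``(theta1 + exp(-theta) - exp(theta1 - theta)) I(theta, t) = h``,
  valid only while ``exp(theta1 - theta) < theta1 + exp(-theta)``; otherwise
  no approximation exists and the solver reports an infinite run length.

No in-control (``theta = 0``) approximation exists for either chart; use
Monte-Carlo simulation instead (see :mod:`cgrcusum.simulate`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import integrate, optimize, stats

from .model import ExponentialBaseline, RiskModel

__all__ = [
    "InformationSpec",
    "fisher_information",
    "cgi_arl_approx",
    "bk_arl_approx",
    "cgi_null_distribution",
]

# fixed stream for Monte-Carlo covariate expectations so that repeated calls
# integrate over the same draws
_MC_SEED = 20220919
_MC_DRAWS = 10_000


@dataclass(frozen=True)
class InformationSpec:
    """Arrival rate, null model, covariate law and hazard ratio for I(theta, t).

    ``covariate_dist`` may be ``None`` (no covariates), a pair
    ``(values, probs)`` of discrete covariate vectors with weights, or any
    object with a ``sample(rng, n) -> (n, p) array`` method (continuous laws,
    integrated by fixed-seed Monte Carlo).
    """

    psi: float
    model: RiskModel
    covariate_dist: object = None
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not self.psi > 0:
            raise ValueError("arrival rate psi must be > 0")
        if self.theta < 0:
            raise ValueError("log hazard ratio theta must be >= 0")

    def _weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Support points and probabilities of ``exp(Z'beta)``."""
        beta = np.asarray(self.model.coefficients, dtype=float)
        if beta.size == 0:
            return np.ones(1), np.ones(1)
        if self.covariate_dist is None:
            raise ValueError(
                "model has coefficients: a covariate distribution is required"
            )
        if isinstance(self.covariate_dist, tuple):
            values, probs = self.covariate_dist
            values = np.atleast_2d(np.asarray(values, dtype=float))
            probs = np.asarray(probs, dtype=float)
            if not math.isclose(float(probs.sum()), 1.0, rel_tol=1e-9):
                raise ValueError("discrete covariate probabilities must sum to 1")
            return np.exp(values @ beta), probs
        rng = np.random.default_rng(_MC_SEED)
        z = np.asarray(self.covariate_dist.sample(rng, _MC_DRAWS), dtype=float)
        return np.exp(np.atleast_2d(z) @ beta), np.full(_MC_DRAWS, 1.0 / _MC_DRAWS)


def fisher_information(spec: InformationSpec, t: float) -> float:
    """Fisher information ``I(theta, t)`` of all observations by time t.

    Exponential baseline without covariates uses the closed form
    ``psi (t - (1 - exp(-exp(theta) lambda t)) / (exp(theta) lambda))``;
    all other cases integrate the expected failure CDF by adaptive
    quadrature.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return 0.0
    base = spec.model.baseline
    if isinstance(base, ExponentialBaseline) and not spec.model.coefficients:
        r = math.exp(spec.theta) * base.rate
        return spec.psi * (t - (-math.expm1(-r * t)) / r)
    w, p = spec._weights()
    e_theta = math.exp(spec.theta)

    def expected_cdf(s):
        return float(np.sum(p * (-np.expm1(-e_theta * w * float(base.cumulative_hazard(s))))))

    val, _ = integrate.quad(expected_cdf, 0.0, t, limit=200)
    return spec.psi * val


def _solve_arl(coefficient: float, h: float, spec: InformationSpec) -> float:
    """Root of ``coefficient * I(theta, t) = h`` in t (bracketing + Brent)."""

    def f(t):
        return coefficient * fisher_information(spec, t) - h

    hi = 365.0
    while f(hi) < 0.0:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("failed to bracket the ARL equation root")
    return optimize.brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-10)


def cgi_arl_approx(theta: float, h: float, spec: InformationSpec) -> float:
    """Approximate out-of-control ARL (days) of the CGI chart; bounds the CGR ARL.

    Solves ``(theta + exp(-theta) - 1) I(theta, t) = h``.  Only defined for
    ``theta > 0``; the in-control run length must be estimated by Monte Carlo.
    """
    if not theta > 0:
        raise ValueError(
            "the drift approximation requires theta > 0; estimate the "
            "in-control ARL by Monte-Carlo simulation instead"
        )
    if not h > 0:
        raise ValueError("control limit h must be > 0")
    coeff = theta + math.exp(-theta) - 1.0
    return _solve_arl(coeff, h, replace(spec, theta=theta))


def bk_arl_approx(theta: float, theta1: float, h: float, spec: InformationSpec) -> float:
    """Approximate out-of-control ARL (days) of the BK chart, or ``inf``.

    Solves ``(theta1 + exp(-theta) - exp(theta1 - theta)) I(theta, t) = h``
    provided ``exp(theta1 - theta) < theta1 + exp(-theta)``; when that
    condition fails the chart has no positive drift approximation and the
    run length is reported as infinite.
    """
    if not theta1 > 0:
        raise ValueError("theta1 must be > 0")
    if not h > 0:
        raise ValueError("control limit h must be > 0")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    coeff = theta1 + math.exp(-theta) - math.exp(theta1 - theta)
    if coeff <= 0.0:
        return math.inf
    return _solve_arl(coeff, h, replace(spec, theta=theta))


def cgi_null_distribution(t: float):
    """Limiting law of ``t * CGI(t)`` under theta = 0: Gamma(shape 1/2, scale t).

    A frozen scipy distribution for diagnostic use.  The statistic also
    carries an asymptotic point mass 1/2 at zero (the MLE sits on the
    boundary whenever ``N(t) <= Lambda(t)``); conditional on being positive,
    ``t * CGI(t)`` follows this gamma law.
    """
    if not t > 0:
        raise ValueError("t must be > 0")
    return stats.gamma(a=0.5, scale=t)
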
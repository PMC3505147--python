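"""Truncated-normal moments and bivariate-normal tail probabilities.

This is the numerical kernel under every design calculation in the package:
eligibility rates ``P(X >= a)``, the mean and variance of baseline severity
among enrollees, and the joint pass rate ``P(X >= a, Z >= b)`` of a two-stage
screen with a correlated surrogate.  All routines are deterministic and smooth
in their arguments so that grid/refinement optimizers behave well.

Conventions
-----------
* ``a = -inf`` (``NEG_INF``) is an explicit "no truncation" sentinel and takes
  an exact code path, not an approximate one.
* A truncation is *degenerate* when the conditioning tail probability falls
  below ``DEGENERATE_TAIL`` (1e-12); hazard-ratio arithmetic loses precision
  beyond that point and a :class:`DegenerateTruncationError` is raised.
* The bivariate upper-rectangle probability uses the Owen's-T closed form,
  accurate to ~1e-15 and symmetric in its arguments by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import ndtr, owens_t
from scipy.stats import norm

from .exceptions import DegenerateTruncationError, InvalidParameterError

__all__ = [
    "NEG_INF",
    "DEGENERATE_TAIL",
    "ScreeningModel",
    "upper_tail",
    "trunc_mean",
    "trunc_var",
    "bvn_upper_rect",
    "cond_upper",
]

NEG_INF = float("-inf")

#: tail probability below which a truncation is declared degenerate
DEGENERATE_TAIL = 1e-12


@dataclass(frozen=True)
class ScreeningModel:
    """Joint distribution of baseline severity X and its prescreen surrogate Z.

    (X, Z) are bivariate normal: ``X ~ N(mu_x, sd_x**2)``,
    ``Z ~ N(mu_z, sd_z**2)`` with correlation ``rho``.  Z is the cheap
    early measurement (phone/mail self-report); X is the on-site screening
    measurement that defines eligibility.
    """

    mu_x: float
    sd_x: float
    mu_z: float
    sd_z: float
    rho: float = 0.0

    def __post_init__(self) -> None:
        if not self.sd_x > 0:
            raise InvalidParameterError(f"sd_x must be > 0, got {self.sd_x}")
        if not self.sd_z > 0:
            raise InvalidParameterError(f"sd_z must be > 0, got {self.sd_z}")
        if not -1.0 < self.rho < 1.0:
            raise InvalidParameterError(f"rho must lie in (-1, 1), got {self.rho}")

    def x_std(self, a: float) -> float:
        """Standardize a threshold on the X scale."""
        return NEG_INF if a == NEG_INF else (a - self.mu_x) / self.sd_x

    def z_std(self, b: float) -> float:
        """Standardize a threshold on the Z scale."""
        return NEG_INF if b == NEG_INF else (b - self.mu_z) / self.sd_z


def _check_sd(sd: float) -> None:
    if not sd > 0:
        raise InvalidParameterError(f"sd must be > 0, got {sd}")


def upper_tail(mu: float, sd: float, a: float) -> float:
    """P(X >= a) for X ~ N(mu, sd**2); 1.0 exactly when a is -inf."""
    _check_sd(sd)
    if a == NEG_INF:
        return 1.0
    return float(ndtr((mu - a) / sd))


def _hazard(alpha: float) -> float:
    # standard-normal hazard phi(alpha)/(1 - Phi(alpha)), log-form for stability
    return math.exp(norm.logpdf(alpha) - norm.logsf(alpha))


def trunc_mean(mu: float, sd: float, a: float) -> float:
    """E[X | X >= a] = mu + sd * h(alpha), alpha = (a - mu)/sd, h the hazard."""
    _check_sd(sd)
    if a == NEG_INF:
        return mu
    alpha = (a - mu) / sd
    if norm.sf(alpha) < DEGENERATE_TAIL:
        raise DegenerateTruncationError(
            f"P(X >= {a}) underflows below {DEGENERATE_TAIL:g}"
        )
    return mu + sd * _hazard(alpha)


def trunc_var(mu: float, sd: float, a: float) -> float:
    """Var(X | X >= a) = sd**2 * (1 + alpha*h(alpha) - h(alpha)**2)."""
    _check_sd(sd)
    if a == NEG_INF:
        return sd * sd
    alpha = (a - mu) / sd
    if norm.sf(alpha) < DEGENERATE_TAIL:
        raise DegenerateTruncationError(
            f"P(X >= {a}) underflows below {DEGENERATE_TAIL:g}"
        )
    h = _hazard(alpha)
    return max(sd * sd * (1.0 + alpha * h - h * h), 0.0)


def _phi2(h: float, k: float, rho: float) -> float:
    """Lower-orthant CDF P(U <= h, V <= k) of correlated standard normals.

    Owen (1956): Phi2(h, k, rho) = (Phi(h) + Phi(k))/2 - T(h, a_h) - T(k, a_k)
    - beta, with T Owen's T function and beta a quadrant correction.  Zero
    arguments are perturbed by 1e-14; Phi2 is continuous so the induced error
    is O(1e-15), well inside the 1e-10 accuracy contract.
    """
    if h == 0.0 and k == 0.0:
        return 0.25 + math.asin(rho) / (2.0 * math.pi)
    eps = 1e-14
    if abs(h) < eps:
        h = eps
    if abs(k) < eps:
        k = eps
    s = math.sqrt(1.0 - rho * rho)
    a_h = (k - rho * h) / (h * s)
    a_k = (h - rho * k) / (k * s)
    beta = 0.0 if h * k > 0.0 else 0.5
    val = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, a_h) - owens_t(k, a_k) - beta
    return min(max(float(val), 0.0), 1.0)


def bvn_upper_rect(u: float, v: float, rho: float) -> float:
    """P(U >= u, V >= v) for standard normals U, V with correlation rho.

    Infinite bounds reduce exactly: both -inf gives 1, one -inf gives the
    marginal upper tail.  ``rho = 0`` takes the exact product path.
    """
    if not -1.0 < rho < 1.0:
        raise InvalidParameterError(f"rho must lie in (-1, 1), got {rho}")
    if u == NEG_INF and v == NEG_INF:
        return 1.0
    if u == NEG_INF:
        return float(ndtr(-v))
    if v == NEG_INF:
        return float(ndtr(-u))
    if rho == 0.0:
        return float(ndtr(-u) * ndtr(-v))
    # upper rectangle = lower-orthant CDF at the reflected point
    return _phi2(-u, -v, rho)


def cond_upper(model: ScreeningModel, a: float, b: float) -> float:
    """P(X >= a | Z >= b) under the bivariate screening model.

    This is the second-stage pass rate among prescreen survivors; it is
    nondecreasing in ``b`` when ``rho > 0`` (a stricter prescreen enriches
    for high X).
    """
    pz = upper_tail(model.mu_z, model.sd_z, b)
    if pz < DEGENERATE_TAIL:
        raise DegenerateTruncationError(
            f"P(Z >= {b}) underflows below {DEGENERATE_TAIL:g}"
        )
    joint = bvn_upper_rect(model.x_std(a), model.z_std(b), model.rho)
    return min(joint / pz, 1.0)
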
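"""Marginal treatment effect and power among severity-enriched enrollees.

The outcome model is a linear interaction model

    Y = beta0 + beta1*Trt + beta2*X + beta3*Trt*X + eps,   eps ~ N(0, sigma^2),

with Trt the randomized treatment indicator and X baseline severity.  When
enrollment is restricted to X >= a, the marginal (two-sample) treatment effect
among enrollees is

    lambda1(a) = beta1 + beta3 * E[X | X >= a],

so with beta1 and beta3 of the same sign the detectable effect grows with the
severity threshold — the rationale for enrichment.  The marginal two-sample
test's power at per-group size n uses the normal approximation

    power(n, a) = Phi( sqrt(n)*|lambda1| / sqrt(V1 + V2) - z_crit ),

where V_g = sigma^2 + slope_g^2 * Var(X | X >= a) are the per-arm outcome
variances among enrollees (slopes beta2 and beta2 + beta3).  ``required_n``
inverts this in closed form; rounding of sample sizes is deliberately left to
the design modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .exceptions import (
    InvalidParameterError,
    SingularSolicitationError,
    UnattainablePowerError,
)
from .gaussian_tails import ScreeningModel, trunc_mean, trunc_var

__all__ = [
    "OutcomeModel",
    "TestSpec",
    "marginal_effect",
    "solve_betas",
    "arm_variances",
    "power",
    "required_n",
    "power_unequal",
]


@dataclass(frozen=True)
class OutcomeModel:
    """Coefficients of the treatment-by-severity interaction model."""

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")

    def null(self) -> "OutcomeModel":
        """The no-treatment-effect version (beta1 = beta3 = 0)."""
        return OutcomeModel(self.beta0, 0.0, self.beta2, 0.0, self.sigma)


@dataclass(frozen=True)
class TestSpec:
    """Two-sided test level, target power, and critical-value convention.

    ``use_z_critical=True`` uses the conventional 1.96 for alpha = 0.05
    (the value design calculations in this field are usually printed with);
    ``False`` uses the exact normal quantile ``Phi^{-1}(1 - alpha/2)``.
    """

    __test__ = False  # domain object, not a pytest case

    alpha: float = 0.05
    target_power: float = 0.90
    use_z_critical: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise InvalidParameterError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.target_power < 1.0:
            raise InvalidParameterError(
                f"target_power must lie in (0, 1), got {self.target_power}"
            )

    @property
    def z_crit(self) -> float:
        if self.use_z_critical and self.alpha == 0.05:
            return 1.96
        return float(norm.isf(self.alpha / 2.0))

    @property
    def z_power(self) -> float:
        return float(norm.ppf(self.target_power))


def marginal_effect(outcome: OutcomeModel, screening: ScreeningModel, a: float) -> float:
    """lambda1(a) = beta1 + beta3 * E[X | X >= a]."""
    if outcome.beta3 == 0.0:
        return outcome.beta1
    return outcome.beta1 + outcome.beta3 * trunc_mean(
        screening.mu_x, screening.sd_x, a
    )


def solve_betas(
    a1: float,
    lam11: float,
    a2: float,
    lam12: float,
    screening: ScreeningModel,
) -> tuple[float, float]:
    """Solicit (beta1, beta3) from two targeted marginal effects.

    Given target effects lam11 at threshold a1 and lam12 at threshold a2,
    solve the 2x2 linear system lam1j = beta1 + beta3 * E[X | X >= aj].
    """
    e1 = trunc_mean(screening.mu_x, screening.sd_x, a1)
    e2 = trunc_mean(screening.mu_x, screening.sd_x, a2)
    if abs(e1 - e2) < 1e-10:
        raise SingularSolicitationError(
            f"truncated means at a1={a1} and a2={a2} coincide; "
            "the two targets do not identify (beta1, beta3)"
        )
    beta1, beta3 = np.linalg.solve(
        np.array([[1.0, e1], [1.0, e2]]), np.array([lam11, lam12])
    )
    return float(beta1), float(beta3)


def arm_variances(
    outcome: OutcomeModel, screening: ScreeningModel, a: float
) -> tuple[float, float]:
    """(Var(Y|X>=a) control, Var(Y|X>=a) treated) among enrollees."""
    vx = trunc_var(screening.mu_x, screening.sd_x, a)
    s2 = outcome.sigma**2
    return (
        s2 + outcome.beta2**2 * vx,
        s2 + (outcome.beta2 + outcome.beta3) ** 2 * vx,
    )


def power(
    n_per_group: float,
    a: float,
    outcome: OutcomeModel,
    screening: ScreeningModel,
    test: TestSpec,
) -> float:
    """Approximate power of the marginal two-sample test at threshold a.

    ``n_per_group`` may be real-valued (it is inverted analytically by
    :func:`required_n`).  A zero marginal effect returns the one-tail size
    value ``Phi(-z_crit)``; detection is two-sided but the opposite-tail
    contribution is negligible at design-relevant powers and is omitted.
    """
    if not n_per_group > 0:
        raise InvalidParameterError(f"n_per_group must be > 0, got {n_per_group}")
    lam = marginal_effect(outcome, screening, a)
    v1, v2 = arm_variances(outcome, screening, a)
    ncp = math.sqrt(n_per_group) * abs(lam) / math.sqrt(v1 + v2)
    return float(norm.cdf(ncp - test.z_crit))


def required_n(
    a: float,
    outcome: OutcomeModel,
    screening: ScreeningModel,
    test: TestSpec,
) -> float:
    """Unrounded per-group sample size achieving the target power at a.

    Closed-form inversion of the power approximation:
    ``n* = ((z_power + z_crit) / |lambda1|)^2 * (V1 + V2)``.
    """
    lam = marginal_effect(outcome, screening, a)
    if lam == 0.0:
        raise UnattainablePowerError(
            f"marginal effect is zero at threshold a={a}; no finite sample "
            "size attains the target power"
        )
    v1, v2 = arm_variances(outcome, screening, a)
    z = test.z_power + test.z_crit
    return (z * z) * (v1 + v2) / (lam * lam)


def power_unequal(
    n1: float,
    n2: float,
    a: float,
    outcome: OutcomeModel,
    screening: ScreeningModel,
    test: TestSpec,
) -> float:
    """Power with unequal allocation (n1 control, n2 treated).

    Noncentrality ``|lambda1| / sqrt(V1/n1 + V2/n2)``; reduces exactly to
    :func:`power` when n1 = n2.
    """
    if not (n1 > 0 and n2 > 0):
        raise InvalidParameterError(f"group sizes must be > 0, got {n1}, {n2}")
    lam = marginal_effect(outcome, screening, a)
    v1, v2 = arm_variances(outcome, screening, a)
    ncp = abs(lam) / math.sqrt(v1 / n1 + v2 / n2)
    return float(norm.cdf(ncp - test.z_crit))
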
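"""One-stage screening design: choose the severity threshold minimizing cost.

With a single screening step on baseline severity X, enrolling subjects with
X >= a at per-group size n requires screening N = n / P(X >= a) per group.
The total-cost objective is

    C(a) = (C_trt + C_placebo) * n(a) + 2 * C_rec * N(a),

with n(a) the unrounded per-group size meeting the power constraint.  Raising
``a`` shrinks the trial (larger marginal effect) but inflates screening; the
trade-off produces a cost curve with an interior minimum, located here by a
grid scan (default step 0.1 on the severity scale) with optional local
refinement.

Rounding convention: the optimizer works on the continuous objective; at the
chosen threshold the enrolled total is rounded *up* (``ceil(2 n*)``,
conservative for power) and the screening total to the *nearest* integer
(``round(2 N*)``), and the reported rounded cost is recomputed from those
integer totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .effect_model import OutcomeModel, TestSpec, marginal_effect, power, required_n
from .exceptions import (
    DegenerateTruncationError,
    InfeasibleGridError,
    InvalidParameterError,
    UnattainablePowerError,
)
from .gaussian_tails import NEG_INF, ScreeningModel, upper_tail

__all__ = [
    "CostStructure",
    "GridSpec",
    "OneStageDesign",
    "FEASIBILITY_FLOOR",
    "ceil_total",
    "round_total",
    "evaluate_onestage",
    "optimize_onestage",
    "onestage_sweep",
    "sweep_recruitment_share",
]

#: grid points with an eligibility rate below this are skipped (screening
#: size divergence)
FEASIBILITY_FLOOR = 1e-4


@dataclass(frozen=True)
class CostStructure:
    """Per-subject unit costs (currency units are carried, not interpreted).

    ``c_rec`` is the one-stage per-screen recruitment cost; ``c_scr`` and
    ``c_pre`` split it into on-site screening and prescreening for the
    two-stage procedure.
    """

    c_trt: float
    c_placebo: float
    c_rec: float = 0.0
    c_scr: float = 0.0
    c_pre: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c_trt", "c_placebo", "c_rec", "c_scr", "c_pre"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(
                    f"{name} must be >= 0, got {getattr(self, name)}"
                )


@dataclass(frozen=True)
class GridSpec:
    """Threshold search grids for the optimizers.

    ``a`` is always the cut on X (screening), ``b`` the cut on Z
    (prescreening).  ``refine`` turns on bounded local refinement of the
    continuous objective around the best grid point.
    """

    a_lo: float
    a_hi: float
    a_step: float = 0.1
    b_lo: float = math.nan
    b_hi: float = math.nan
    b_step: float = 0.1
    refine: bool = False

    def __post_init__(self) -> None:
        self._check("a", self.a_lo, self.a_hi, self.a_step)
        if not math.isnan(self.b_lo) or not math.isnan(self.b_hi):
            self._check("b", self.b_lo, self.b_hi, self.b_step)

    @staticmethod
    def _check(tag: str, lo: float, hi: float, step: float) -> None:
        if not (lo < hi):
            raise InvalidParameterError(f"{tag}_lo must be < {tag}_hi ({lo} !< {hi})")
        if not step > 0:
            raise InvalidParameterError(f"{tag}_step must be > 0, got {step}")
        if (hi - lo) / step < 1.0:
            raise InvalidParameterError(f"{tag} grid must contain at least 2 points")

    @classmethod
    def default_for(cls, screening: ScreeningModel, step: float = 0.1,
                    refine: bool = False) -> "GridSpec":
        """Mean +/- 3 SD on each scale, matching one-decimal reporting."""
        return cls(
            a_lo=screening.mu_x - 3 * screening.sd_x,
            a_hi=screening.mu_x + 3 * screening.sd_x,
            a_step=step,
            b_lo=screening.mu_z - 3 * screening.sd_z,
            b_hi=screening.mu_z + 3 * screening.sd_z,
            b_step=step,
            refine=refine,
        )

    @staticmethod
    def _points(lo: float, hi: float, step: float) -> np.ndarray:
        n = int(round((hi - lo) / step)) + 1
        return np.round(np.linspace(lo, lo + (n - 1) * step, n), 10)

    def a_grid(self) -> np.ndarray:
        return self._points(self.a_lo, self.a_hi, self.a_step)

    def b_grid(self) -> np.ndarray:
        if math.isnan(self.b_lo):
            raise InvalidParameterError("no b-grid configured")
        return self._points(self.b_lo, self.b_hi, self.b_step)


def ceil_total(x: float) -> int:
    """Round a combined (both-arm) size up, with a 1e-9 guard for float noise."""
    return int(math.ceil(x - 1e-9))


def round_total(x: float) -> int:
    """Round a combined size to the nearest integer (half away from zero)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class OneStageDesign:
    """A fully evaluated one-stage design at a given severity threshold."""

    a_opt: float
    n_star: float
    N_star: float
    n_total: int
    N_total: int
    cost_unrounded: float
    cost_rounded: float
    lambda1: float
    power_achieved: float

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_onestage(
    a: float,
    outcome: OutcomeModel,
    screening: ScreeningModel,
    costs: CostStructure,
    test: TestSpec,
) -> OneStageDesign:
    """Size and cost of the one-stage design with threshold fixed at ``a``."""
    n_star = required_n(a, outcome, screening, test)
    p = upper_tail(screening.mu_x, screening.sd_x, a)
    if p < FEASIBILITY_FLOOR:
        raise DegenerateTruncationError(
            f"P(X >= {a}) = {p:.3g} below feasibility floor {FEASIBILITY_FLOOR}"
        )
    N_star = n_star / p
    cost_unrounded = (costs.c_trt + costs.c_placebo) * n_star + 2 * costs.c_rec * N_star
    n_total = ceil_total(2 * n_star)
    N_total = round_total(2 * N_star)
    cost_rounded = (
        (costs.c_trt + costs.c_placebo) / 2.0 * n_total + costs.c_rec * N_total
    )
    return OneStageDesign(
        a_opt=float(a),
        n_star=float(n_star),
        N_star=float(N_star),
        n_total=n_total,
        N_total=N_total,
        cost_unrounded=float(cost_unrounded),
        cost_rounded=float(cost_rounded),
        lambda1=float(marginal_effect(outcome, screening, a)),
        power_achieved=float(power(n_total / 2.0, a, outcome, screening, test)),
    )


def _cost_unrounded(a, outcome, screening, costs, test) -> float:
    n_star = required_n(a, outcome, screening, test)
    p = upper_tail(screening.mu_x, screening.sd_x, a)
    return (costs.c_trt + costs.c_placebo) * n_star + 2 * costs.c_rec * n_star / p


def optimize_onestage(
    outcome: OutcomeModel,
    screening: ScreeningModel,
    costs: CostStructure,
    test: TestSpec,
    grid: GridSpec | None = None,
) -> OneStageDesign:
    """Minimize the continuous one-stage cost over the threshold grid.

    Ties are broken toward smaller ``a`` (less restrictive eligibility at
    equal cost); infeasible or degenerate points are skipped.
    """
    if grid is None:
        grid = GridSpec.default_for(screening)
    best_a = None
    best_cost = math.inf
    for a in grid.a_grid():
        if upper_tail(screening.mu_x, screening.sd_x, a) < FEASIBILITY_FLOOR:
            continue
        try:
            cost = _cost_unrounded(a, outcome, screening, costs, test)
        except (DegenerateTruncationError, UnattainablePowerError):
            continue
        if cost < best_cost - 1e-12:
            best_cost, best_a = cost, float(a)
    if best_a is None:
        raise InfeasibleGridError("no feasible threshold on the a-grid")
    if grid.refine:
        lo, hi = best_a - grid.a_step, best_a + grid.a_step
        res = minimize_scalar(
            lambda a: _cost_unrounded(a, outcome, screening, costs, test),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if res.fun < best_cost:
            best_a = float(res.x)
    return evaluate_onestage(best_a, outcome, screening, costs, test)


def onestage_sweep(
    outcome: OutcomeModel,
    screening: ScreeningModel,
    costs: CostStructure,
    test: TestSpec,
    grid: GridSpec | None = None,
) -> pd.DataFrame:
    """Evaluate the design at every feasible grid threshold (cost/size curves).

    One row per threshold ``a``; this is the table behind cost-versus-threshold
    and size-versus-threshold plots.
    """
    if grid is None:
        grid = GridSpec.default_for(screening)
    rows = []
    for a in grid.a_grid():
        if upper_tail(screening.mu_x, screening.sd_x, a) < FEASIBILITY_FLOOR:
            continue
        try:
            d = evaluate_onestage(a, outcome, screening, costs, test)
        except (DegenerateTruncationError, UnattainablePowerError):
            continue
        rows.append(
            {
                "a": float(a),
                "lambda1": d.lambda1,
                "n_star": d.n_star,
                "N_star": d.N_star,
                "n_total": d.n_total,
                "N_total": d.N_total,
                "cost_unrounded": d.cost_unrounded,
                "cost_rounded": d.cost_rounded,
            }
        )
    return pd.DataFrame(rows)


def sweep_recruitment_share(
    shares: "list[float]",
    outcome: OutcomeModel,
    screening: ScreeningModel,
    test: TestSpec,
    grid: GridSpec | None = None,
    bundle: float = 1000.0,
) -> pd.DataFrame:
    """Re-optimize while shifting cost weight from intervention to screening.

    Each share s splits a fixed per-subject bundle into recruitment
    ``c_rec = s * bundle`` and intervention ``c_trt = c_placebo =
    (1 - s) * bundle``.  As screening is weighted more heavily the optimum
    total cost rises and the optimum screening size falls.
    """
    rows = []
    for s in shares:
        costs = CostStructure(
            c_trt=(1.0 - s) * bundle, c_placebo=(1.0 - s) * bundle, c_rec=s * bundle
        )
        d = optimize_onestage(outcome, screening, costs, test, grid)
        rows.append(
            {
                "share": float(s),
                "c_rec": costs.c_rec,
                "c_trt": costs.c_trt,
                "a_opt": d.a_opt,
                "N_total": d.N_total,
                "n_total": d.n_total,
                "cost_unrounded": d.cost_unrounded,
                "cost_rounded": d.cost_rounded,
            }
        )
    return pd.DataFrame(rows)
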
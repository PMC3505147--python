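"""Two-stage screening design: prescreen on a surrogate, then screen on X.

The first stage prescreens cheap surrogate measurements Z >= b; survivors get
the expensive on-site screen and enroll if X >= a.  Per group, prescreening M
candidates yields N = M * P(Z >= b) screens and n = M * P(X >= a, Z >= b)
enrollees.  Since the power constraint involves only ``a`` (the test is run
among X >= a enrollees), n(a) is fixed per outer threshold and the total cost

    C(a, b) = n(a) * [ C_trt + C_placebo
                       + 2 C_scr / P(X >= a | Z >= b)
                       + 2 C_pre / P(X >= a, Z >= b) ]

is scanned over a nested (a, b) grid.  A correlated surrogate (rho > 0) lets
a prescreen cut concentrate expensive screens on likely-eligible candidates;
the resulting optimum never costs more than the one-stage optimum when
``c_pre + c_scr = c_rec``.

Threshold semantics: ``a`` is ALWAYS the on-X (second-stage) cut and ``b``
the on-Z (prescreen) cut.  Savings are computed against the one-stage optimum
run at the same combined per-subject recruitment cost, on the rounded costs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace

import pandas as pd

from .effect_model import OutcomeModel, TestSpec, marginal_effect, power, required_n
from .exceptions import (
    DegenerateTruncationError,
    InfeasibleGridError,
    InfeasiblePointError,
    UnattainablePowerError,
)
from .gaussian_tails import (
    DEGENERATE_TAIL,
    ScreeningModel,
    bvn_upper_rect,
    upper_tail,
)
from .onestage import (
    FEASIBILITY_FLOOR,
    CostStructure,
    GridSpec,
    OneStageDesign,
    ceil_total,
    optimize_onestage,
    round_total,
)

__all__ = [
    "TwoStageDesign",
    "total_cost_twostage",
    "optimize_b_given_a",
    "optimize_twostage",
    "twostage_sweep",
    "sweep_prescreen_share",
    "sweep_rho",
]


@dataclass(frozen=True)
class TwoStageDesign:
    """A fully evaluated two-stage design.

    ``saving_abs``/``saving_pct`` compare the rounded cost against the
    one-stage optimum at combined recruitment cost ``c_scr + c_pre`` (NaN when
    the comparison was not requested).
    """

    a_opt: float
    b_opt: float
    n_star: float
    N_star: float
    M_star: float
    n_total: int
    N_total: int
    M_total: int
    cost_unrounded: float
    cost_rounded: float
    saving_abs: float
    saving_pct: float
    lambda1: float
    power_achieved: float

    def to_dict(self) -> dict:
        return asdict(self)


def _joint_and_cond(
    screening: ScreeningModel, a: float, b: float
) -> tuple[float, float]:
    joint = bvn_upper_rect(screening.x_std(a), screening.z_std(b), screening.rho)
    pz = upper_tail(screening.mu_z, screening.sd_z, b)
    if joint < DEGENERATE_TAIL or pz < DEGENERATE_TAIL:
        raise InfeasiblePointError(
            f"joint tail P(X>={a}, Z>={b}) = {joint:.3g} is degenerate"
        )
    return joint, joint / pz


def total_cost_twostage(
    a: float,
    b: float,
    outcome: OutcomeModel,
    screening: ScreeningModel,
    costs: CostStructure,
    test: TestSpec,
) -> float:
    """Continuous total cost of the two-stage design at thresholds (a, b).

    Power involves only ``a``, so ``n = required_n(a)`` regardless of the
    prescreen cut.
    """
    n = required_n(a, outcome, screening, test)
    joint, cond = _joint_and_cond(screening, a, b)
    return n * (
        costs.c_trt + costs.c_placebo + 2 * costs.c_scr / cond + 2 * costs.c_pre / joint
    )


def optimize_b_given_a(
    a: float,
    outcome: OutcomeModel,
    screening: ScreeningModel,
    costs: CostStructure,
    test: TestSpec,
    grid: GridSpec | None = None,
) -> tuple[float, float]:
    """Best prescreen cut for a fixed screening threshold: (b_opt, cost).

    Ties break toward smaller ``b`` (lighter prescreen filtering).  Points
    with joint pass rate below the feasibility floor are skipped.
    """
    if grid is None:
        grid = GridSpec.default_for(screening)
    n = required_n(a, outcome, screening, test)
    fixed = n * (costs.c_trt + costs.c_placebo)
    best_b, best_cost = None, math.inf
    for b in grid.b_grid():
        joint = bvn_upper_rect(screening.x_std(a), screening.z_std(b), screening.rho)
        if joint < FEASIBILITY_FLOOR:
            continue
        pz = upper_tail(screening.mu_z, screening.sd_z, b)
        cost = fixed + 2 * n * (costs.c_scr * pz + costs.c_pre) / joint
        if cost < best_cost - 1e-12:
            best_cost, best_b = cost, float(b)
    if best_b is None:
        raise InfeasibleGridError(f"no feasible prescreen cut for a={a}")
    return best_b, best_cost


def _evaluate(
    a: float,
    b: float,
    outcome: OutcomeModel,
    screening: ScreeningModel,
    costs: CostStructure,
    test: TestSpec,
    onestage_ref: OneStageDesign | None,
) -> TwoStageDesign:
    n_star = required_n(a, outcome, screening, test)
    joint, cond = _joint_and_cond(screening, a, b)
    N_star = n_star / cond
    M_star = n_star / joint
    cost_unrounded = n_star * (
        costs.c_trt + costs.c_placebo + 2 * costs.c_scr / cond + 2 * costs.c_pre / joint
    )
    n_total = ceil_total(2 * n_star)
    N_total = round_total(2 * N_star)
    M_total = round_total(2 * M_star)
    cost_rounded = (
        (costs.c_trt + costs.c_placebo) / 2.0 * n_total
        + costs.c_scr * N_total
        + costs.c_pre * M_total
    )
    if onestage_ref is not None:
        saving_abs = onestage_ref.cost_rounded - cost_rounded
        saving_pct = 100.0 * saving_abs / onestage_ref.cost_rounded
    else:
        saving_abs = saving_pct = math.nan
    return TwoStageDesign(
        a_opt=float(a),
        b_opt=float(b),
        n_star=float(n_star),
        N_star=float(N_star),
        M_star=float(M_star),
        n_total=n_total,
        N_total=N_total,
        M_total=M_total,
        cost_unrounded=float(cost_unrounded),
        cost_rounded=float(cost_rounded),
        saving_abs=float(saving_abs),
        saving_pct=float(saving_pct),
        lambda1=float(marginal_effect(outcome, screening, a)),
        power_achieved=float(power(n_total / 2.0, a, outcome, screening, test)),
    )


def optimize_twostage(
    outcome: OutcomeModel,
    screening: ScreeningModel,
    costs: CostStructure,
    test: TestSpec,
    grid: GridSpec | None = None,
    compare_onestage: bool = True,
) -> TwoStageDesign:
    """Nested grid scan (outer a, inner b) of the continuous cost objective.

    Ties break toward smaller ``a`` then smaller ``b``.  When
    ``compare_onestage`` is set, the one-stage optimum at recruitment cost
    ``c_scr + c_pre`` is solved on the same a-grid and the rounded-cost
    saving is reported.
    """
    if grid is None:
        grid = GridSpec.default_for(screening)
    best = None
    best_cost = math.inf
    b_grid = grid.b_grid()
    for a in grid.a_grid():
        if upper_tail(screening.mu_x, screening.sd_x, a) < FEASIBILITY_FLOOR:
            continue
        try:
            n = required_n(a, outcome, screening, test)
        except (DegenerateTruncationError, UnattainablePowerError):
            continue
        fixed = n * (costs.c_trt + costs.c_placebo)
        ua = screening.x_std(a)
        for b in b_grid:
            joint = bvn_upper_rect(ua, screening.z_std(b), screening.rho)
            if joint < FEASIBILITY_FLOOR:
                continue
            pz = upper_tail(screening.mu_z, screening.sd_z, b)
            cost = fixed + 2 * n * (costs.c_scr * pz + costs.c_pre) / joint
            if cost < best_cost - 1e-12:
                best_cost, best = cost, (float(a), float(b))
    if best is None:
        raise InfeasibleGridError("no feasible (a, b) pair on the grid")
    onestage_ref = None
    if compare_onestage:
        onestage_ref = optimize_onestage(
            outcome,
            screening,
            replace(costs, c_rec=costs.c_scr + costs.c_pre),
            test,
            grid,
        )
    return _evaluate(best[0], best[1], outcome, screening, costs, test, onestage_ref)


def twostage_sweep(
    outcome: OutcomeModel,
    screening: ScreeningModel,
    costs: CostStructure,
    test: TestSpec,
    grid: GridSpec | None = None,
) -> pd.DataFrame:
    """Per-threshold curves of the two-stage design (b optimized out).

    One row per feasible screening threshold ``a`` with the best prescreen
    cut, sizes, and costs — the table behind two-stage versus one-stage
    comparison plots.
    """
    if grid is None:
        grid = GridSpec.default_for(screening)
    rows = []
    for a in grid.a_grid():
        if upper_tail(screening.mu_x, screening.sd_x, a) < FEASIBILITY_FLOOR:
            continue
        try:
            b_opt, _ = optimize_b_given_a(a, outcome, screening, costs, test, grid)
            d = _evaluate(a, b_opt, outcome, screening, costs, test, None)
        except (DegenerateTruncationError, UnattainablePowerError, InfeasibleGridError):
            continue
        rows.append(
            {
                "a": float(a),
                "b_opt": d.b_opt,
                "n_star": d.n_star,
                "N_star": d.N_star,
                "M_star": d.M_star,
                "n_total": d.n_total,
                "N_total": d.N_total,
                "M_total": d.M_total,
                "cost_unrounded": d.cost_unrounded,
                "cost_rounded": d.cost_rounded,
            }
        )
    return pd.DataFrame(rows)


def sweep_prescreen_share(
    shares: "list[float]",
    outcome: OutcomeModel,
    screening: ScreeningModel,
    test: TestSpec,
    grid: GridSpec | None = None,
    recruit_bundle: float = 300.0,
    c_trt: float = 700.0,
    c_placebo: float = 700.0,
) -> pd.DataFrame:
    """Optimum cost as the prescreen share of a fixed recruitment bundle varies.

    Each share s splits the bundle into ``c_pre = s * bundle`` and
    ``c_scr = (1 - s) * bundle``.  The cheaper prescreening is relative to
    screening, the larger the saving, so the optimum cost is nondecreasing
    in the share.
    """
    rows = []
    for s in shares:
        costs = CostStructure(
            c_trt=c_trt,
            c_placebo=c_placebo,
            c_scr=(1.0 - s) * recruit_bundle,
            c_pre=s * recruit_bundle,
        )
        d = optimize_twostage(outcome, screening, costs, test, grid,
                              compare_onestage=False)
        rows.append(
            {
                "share": float(s),
                "c_pre": costs.c_pre,
                "c_scr": costs.c_scr,
                "rho": screening.rho,
                "a_opt": d.a_opt,
                "b_opt": d.b_opt,
                "cost_unrounded": d.cost_unrounded,
                "cost_rounded": d.cost_rounded,
            }
        )
    return pd.DataFrame(rows)


def sweep_rho(
    rhos: "list[float]",
    outcome: OutcomeModel,
    screening: ScreeningModel,
    costs: CostStructure,
    test: TestSpec,
    grid: GridSpec | None = None,
) -> pd.DataFrame:
    """Optimum cost as surrogate quality (correlation rho) varies.

    A stronger surrogate concentrates screening on likely enrollees, so the
    optimum cost is nonincreasing in rho (for rho >= 0).
    """
    rows = []
    for r in rhos:
        scr = replace(screening, rho=float(r))
        d = optimize_twostage(outcome, scr, costs, test, grid,
                              compare_onestage=False)
        rows.append(
            {
                "rho": float(r),
                "c_pre": costs.c_pre,
                "c_scr": costs.c_scr,
                "a_opt": d.a_opt,
                "b_opt": d.b_opt,
                "cost_unrounded": d.cost_unrounded,
                "cost_rounded": d.cost_rounded,
            }
        )
    return pd.DataFrame(rows)
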
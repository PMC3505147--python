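"""Monte-Carlo verification of designed trials.

Each replicate simulates the full pipeline: draw bivariate-normal (Z, X)
candidates, apply the prescreen cut (two-stage only) and the screening cut,
enroll until the designed total is met, randomize 1:1, generate outcomes from
the interaction model, and run a two-sample Welch t-test.  Aggregating
replicates yields empirical power, empirical type-I error, and the realized
cost distribution — the stochastic counterpart of the deterministic design
calculations.

Recruitment modes
-----------------
``sequential`` (default)
    Candidates are drawn until the enrollment target is met, so realized
    prescreen/screen counts are random; mean realized cost slightly exceeds
    the calculated cost because enrolled totals are rounded up.
``fixed_sizes``
    Exactly the designed (rounded) number of candidates is drawn and every
    eligible one enrolls; realized enrollment is then random.

Reproducibility: one master seed feeds a ``numpy.random.SeedSequence`` spawn
tree, so replicates are mutually independent and the whole summary is
bit-reproducible for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .effect_model import OutcomeModel, TestSpec
from .exceptions import InvalidParameterError, RecruitmentFailureError
from .gaussian_tails import NEG_INF, ScreeningModel, bvn_upper_rect
from .onestage import CostStructure, OneStageDesign
from .twostage import TwoStageDesign

__all__ = [
    "SimulationSpec",
    "TrialResult",
    "SimulationSummary",
    "simulate_candidates",
    "run_trial",
    "estimate_operating_characteristics",
]

#: hard cap on candidate draws per replicate
CANDIDATE_BUDGET = 10_000_000


@dataclass(frozen=True)
class SimulationSpec:
    """Replication count, master seed, and recruitment behaviour."""

    replicates: int = 10_000
    seed: int = 0
    null_model: bool = False
    recruitment_mode: str = "sequential"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise InvalidParameterError(
                f"replicates must be >= 1, got {self.replicates}"
            )
        if self.recruitment_mode not in ("sequential", "fixed_sizes"):
            raise InvalidParameterError(
                f"recruitment_mode must be 'sequential' or 'fixed_sizes', "
                f"got {self.recruitment_mode!r}"
            )


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one simulated trial."""

    reject: bool
    realized_cost: float
    lambda_hat: float
    n_prescreened: int
    n_screened: int
    n_enrolled: int


@dataclass(frozen=True)
class SimulationSummary:
    """Aggregated operating characteristics over seeded replicates.

    ``empirical_power`` is the rejection rate under the configured outcome
    model (NaN when ``null_model`` ran instead); ``empirical_size`` is the
    rejection rate under the matched no-effect model, estimated from an
    independent seed stream.  ``se_*`` are Monte-Carlo standard errors.
    """

    empirical_power: float
    empirical_size: float
    mean_cost: float
    sd_cost: float
    mean_lambda_hat: float
    replicates_used: int
    seed: int
    se_power: float
    se_size: float
    se_cost: float
    recruitment_failures: int

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_candidates(
    m: int, screening: ScreeningModel, seed: "int | np.random.Generator"
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``m`` paired (Z, X) candidates from the bivariate screening model.

    Uses the conditional decomposition Z ~ N(mu_z, sd_z^2),
    X | Z ~ N(mu_x + rho sd_x (Z - mu_z)/sd_z, sd_x^2 (1 - rho^2)).
    """
    if m < 1:
        raise InvalidParameterError(f"m must be >= 1, got {m}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    e1 = rng.standard_normal(m)
    e2 = rng.standard_normal(m)
    z = screening.mu_z + screening.sd_z * e1
    x = (
        screening.mu_x
        + screening.rho * screening.sd_x * e1
        + screening.sd_x * math.sqrt(1.0 - screening.rho**2) * e2
    )
    return z, x


def _design_cuts(design) -> tuple[float, float, bool]:
    """(a, b, is_two_stage) for either design flavour."""
    if isinstance(design, TwoStageDesign):
        return design.a_opt, design.b_opt, True
    if isinstance(design, OneStageDesign):
        return design.a_opt, NEG_INF, False
    raise InvalidParameterError(f"unsupported design object {type(design)!r}")


def _recruit(design, screening, mode, rng):
    """Recruit one trial's worth of subjects; returns counts and enrollee X."""
    a, b, two_stage = _design_cuts(design)
    target = design.n_total
    p_joint = bvn_upper_rect(screening.x_std(a), screening.z_std(b), screening.rho)

    if mode == "fixed_sizes":
        m_draw = design.M_total if two_stage else design.N_total
        z, x = simulate_candidates(m_draw, screening, rng)
        pre_pass = z >= b if two_stage else np.ones(m_draw, dtype=bool)
        both = pre_pass & (x >= a)
        enrolled_x = x[both][:target]
        return m_draw, int(pre_pass.sum()), enrolled_x

    # sequential: draw in chunks until the target number of enrollees is met
    z_parts, x_parts = [], []
    drawn = enrolled = 0
    while enrolled < target:
        need = target - enrolled
        chunk = int(need / max(p_joint, 1e-6) * 1.3) + 32
        chunk = min(chunk, CANDIDATE_BUDGET - drawn)
        if chunk <= 0:
            raise RecruitmentFailureError(
                f"candidate budget {CANDIDATE_BUDGET} exhausted before "
                f"{target} enrollees were found"
            )
        z, x = simulate_candidates(chunk, screening, rng)
        z_parts.append(z)
        x_parts.append(x)
        drawn += chunk
        enrolled += int(((z >= b) & (x >= a)).sum())
    z = np.concatenate(z_parts)
    x = np.concatenate(x_parts)
    both = (z >= b) & (x >= a)
    # index of the target-th enrollee: recruitment stops right there
    stop = int(np.nonzero(both)[0][target - 1])
    n_pre = stop + 1
    n_scr = int((z[: stop + 1] >= b).sum()) if two_stage else n_pre
    enrolled_x = x[: stop + 1][both[: stop + 1]]
    return n_pre, n_scr, enrolled_x


def run_trial(
    design: "OneStageDesign | TwoStageDesign",
    outcome: OutcomeModel,
    screening: ScreeningModel,
    costs: CostStructure,
    test: TestSpec,
    sim: SimulationSpec,
    seed: "int | np.random.Generator",
    use_normal_critical: bool = False,
) -> TrialResult:
    """Simulate one recruit-randomize-test cycle of the designed trial.

    The analysis is Welch's two-sample t-test (separate per-arm variances,
    Satterthwaite degrees of freedom); ``use_normal_critical`` compares the
    Welch statistic against the normal critical value instead, matching the
    design-stage power approximation.
    """
    if design.n_total < 4:
        raise InvalidParameterError("design must enroll at least 2 per arm")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a, b, two_stage = _design_cuts(design)
    eff = outcome.null() if sim.null_model else outcome

    n_pre, n_scr, enrolled_x = _recruit(design, screening, sim.recruitment_mode, rng)
    n_enr = enrolled_x.size
    if n_enr < 4:
        raise RecruitmentFailureError(
            f"only {n_enr} enrollees recruited; need at least 2 per arm"
        )

    # 1:1 randomization (odd totals put the extra subject in the treated arm)
    trt = np.zeros(n_enr, dtype=bool)
    trt[rng.permutation(n_enr)[: n_enr - n_enr // 2]] = True
    y = (
        eff.beta0
        + eff.beta1 * trt
        + eff.beta2 * enrolled_x
        + eff.beta3 * trt * enrolled_x
        + eff.sigma * rng.standard_normal(n_enr)
    )
    y_t, y_c = y[trt], y[~trt]
    if use_normal_critical:
        t_stat = (y_t.mean() - y_c.mean()) / math.sqrt(
            y_t.var(ddof=1) / y_t.size + y_c.var(ddof=1) / y_c.size
        )
        reject = abs(t_stat) > test.z_crit
    else:
        reject = stats.ttest_ind(y_t, y_c, equal_var=False).pvalue < test.alpha

    n_t, n_c = int(trt.sum()), int(n_enr - trt.sum())
    if two_stage:
        recruit_cost = costs.c_pre * n_pre + costs.c_scr * n_scr
    else:
        recruit_cost = costs.c_rec * n_scr
    realized_cost = recruit_cost + costs.c_trt * n_t + costs.c_placebo * n_c
    return TrialResult(
        reject=bool(reject),
        realized_cost=float(realized_cost),
        lambda_hat=float(y_t.mean() - y_c.mean()),
        n_prescreened=int(n_pre),
        n_screened=int(n_scr),
        n_enrolled=int(n_enr),
    )


def _rejection_stream(
    design, outcome, screening, costs, test, sim, seed_seq, collect, use_normal_critical
):
    rejects, costs_out, lams = [], [], []
    failures = 0
    for child in seed_seq.spawn(sim.replicates):
        rng = np.random.default_rng(child)
        try:
            res = run_trial(
                design, outcome, screening, costs, test, sim, rng,
                use_normal_critical=use_normal_critical,
            )
        except RecruitmentFailureError:
            failures += 1
            continue
        rejects.append(res.reject)
        if collect:
            costs_out.append(res.realized_cost)
            lams.append(res.lambda_hat)
    return np.asarray(rejects, dtype=bool), np.asarray(costs_out), np.asarray(lams), failures


def estimate_operating_characteristics(
    design: "OneStageDesign | TwoStageDesign",
    outcome: OutcomeModel,
    screening: ScreeningModel,
    costs: CostStructure,
    test: TestSpec,
    sim: SimulationSpec,
    use_normal_critical: bool = False,
    include_size: bool = True,
) -> SimulationSummary:
    """Empirical power, type-I error, and realized-cost distribution.

    Runs ``sim.replicates`` trials under the configured outcome model (or its
    null version when ``sim.null_model``) and, when ``include_size``, the same
    number again under the matched null from an independent seed stream.
    Replicates whose recruitment fails are dropped and counted.
    """
    root = np.random.SeedSequence(sim.seed)
    power_ss, size_ss = root.spawn(2)

    rejects, rcosts, lams, failures = _rejection_stream(
        design, outcome, screening, costs, test, sim, power_ss, True,
        use_normal_critical,
    )
    used = rejects.size
    p_hat = float(rejects.mean()) if used else math.nan
    se_p = math.sqrt(p_hat * (1 - p_hat) / used) if used else math.nan

    if include_size and not sim.null_model:
        null_sim = SimulationSpec(
            sim.replicates, sim.seed, True, sim.recruitment_mode
        )
        srej, _, _, sfail = _rejection_stream(
            design, outcome, screening, costs, test, null_sim, size_ss, False,
            use_normal_critical,
        )
        failures += sfail
        size_hat = float(srej.mean()) if srej.size else math.nan
        se_size = (
            math.sqrt(size_hat * (1 - size_hat) / srej.size) if srej.size else math.nan
        )
    elif sim.null_model:
        # the main stream already ran under the null
        size_hat, se_size, p_hat, se_p = p_hat, se_p, math.nan, math.nan
    else:
        size_hat = se_size = math.nan

    return SimulationSummary(
        empirical_power=p_hat,
        empirical_size=size_hat,
        mean_cost=float(rcosts.mean()) if used else math.nan,
        sd_cost=float(rcosts.std(ddof=1)) if used > 1 else math.nan,
        mean_lambda_hat=float(lams.mean()) if used else math.nan,
        replicates_used=int(used),
        seed=sim.seed,
        se_power=se_p,
        se_size=se_size,
        se_cost=float(rcosts.std(ddof=1) / math.sqrt(used)) if used > 1 else math.nan,
        recruitment_failures=int(failures),
    )
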
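# Methods

## Problem and model

`trialcost` plans randomized two-arm trials in which the treatment effect is
believed to grow with baseline symptom severity. Severity after treatment is
modelled as

    Y = beta0 + beta1*Trt + beta2*X + beta3*Trt*X + eps,   eps ~ N(0, sigma^2),

with `Trt` the randomized arm indicator and `X` the baseline severity,
independent of `eps`. Directly powering a trial for the interaction `beta3`
is usually infeasible, so the design instead enrolls only subjects with
`X >= a` and tests the *marginal* effect with a two-sample t-test. Among
enrollees the arm-mean difference is

    lambda1(a) = beta1 + beta3 * E[X | X >= a],

which (for `beta1`, `beta3` of the same sign) grows in magnitude with the
threshold: stricter eligibility buys a larger detectable effect and hence a
smaller trial, at the price of screening more candidates. The package turns
that trade-off into an explicit cost minimization.

Power uses the normal approximation to the two-sample test,

    power(n, a) = Phi( sqrt(n) |lambda1(a)| / sqrt(V1 + V2) - z_crit ),
    V_g = sigma^2 + slope_g^2 * Var(X | X >= a),

with per-arm outcome slopes `beta2` (control) and `beta2 + beta3` (treated),
`n` the per-group size. Note that truncation shrinks `Var(X | X >= a)`, so
raising `a` reduces the required `n` through *two* channels: a larger
`|lambda1|` and a smaller outcome variance. The closed-form inversion
`n*(a) = ((z_power + z_crit) / |lambda1|)^2 (V1 + V2)` returns an unrounded
per-group size; all rounding is deferred to the design layer so the
convention lives in one place.

Assumptions worth keeping in mind: normal outcome errors and (jointly)
normal screening variables; a moderate-to-large sample normal approximation
in place of the exact noncentral-t; equal allocation by default (an
unequal-allocation power generalization `power_unequal` is provided);
enrollment restricted to `X >= a` means conclusions generalize only to that
subpopulation.

## Cost objectives

One-stage: screening `N = n / P(X >= a)` candidates per group at unit cost
`c_rec` gives

    C1(a) = (c_trt + c_placebo) n(a) + 2 c_rec N(a).

Two-stage: a cheap prescreen on a surrogate `Z` (correlation `rho` with X)
at cut `b` filters candidates before the expensive screen. Per group,
prescreening M yields `N = M P(Z >= b)` screens and
`n = M P(X >= a, Z >= b)` enrollees, so

    C2(a, b) = n(a) [ c_trt + c_placebo
                      + 2 c_scr / P(X >= a | Z >= b)
                      + 2 c_pre / P(X >= a, Z >= b) ].

Power involves only `a` (the analysis is run among X-eligible enrollees and
deliberately ignores the `Z >= b` conditioning), so `n(a)` is shared between
procedures and the inner optimization over `b` is a cheap 1-D scan. With
`c_pre + c_scr = c_rec` the two-stage optimum can never exceed the one-stage
optimum, because `b -> -inf` reproduces it.

## Numerical kernel

* Tails and truncated moments use the standard-normal hazard
  `h(alpha) = phi(alpha)/(1 - Phi(alpha))` evaluated in log form:
  `E[X|X>=a] = mu + sd*h`, `Var(X|X>=a) = sd^2 (1 + alpha h - h^2)`.
  A truncation is declared degenerate when the conditioning tail falls below
  1e-12, where this arithmetic loses precision.
* The bivariate upper-rectangle probability `P(U>=u, V>=v)` is computed from
  the Owen's-T closed form for the bivariate normal CDF
  (`scipy.special.owens_t`): deterministic, smooth, and accurate to ~1e-15,
  which grid optimizers and tie-breaking rely on. Zero arguments are
  perturbed by 1e-14 (the CDF is continuous, so the induced error is below
  1e-14). Tests cross-check against adaptive quadrature of the
  conditional-normal form, `scipy.stats.multivariate_normal`, and seeded
  Monte-Carlo.
* `-inf` is an explicit sentinel for "no truncation" with exact code paths.
* The critical value defaults to the conventional printed 1.96 for
  `alpha = 0.05` (`TestSpec.use_z_critical`); the exact `Phi^{-1}(1-alpha/2)`
  is a flag away. Design tables in this field are computed with 1.96, and the
  difference is invisible at reporting precision.

## Optimization and rounding conventions

* Default grids span mean +/- 3 SD on each scale at step 0.1, matching the
  one-decimal convention for reporting thresholds. Optional bounded local
  refinement (`GridSpec.refine`) polishes the continuous objective; it is off
  by default because reported optima are one-decimal.
* Grid points with eligibility (or joint pass) probability below 1e-4 are
  skipped: screening sizes diverge there, and with a free prescreen
  (`c_pre = 0`) the objective would otherwise push `b` to infinity.
* Ties break toward smaller thresholds: less restrictive eligibility is
  preferred at equal cost.
* The optimizer minimizes the *continuous* objective. At the chosen
  thresholds, integer totals are derived as `n_total = ceil(2 n*)`
  (conservative for power) and `N_total`, `M_total = round(2 N*)`,
  `round(2 M*)` (nearest), and the rounded cost is recomputed from those
  integers. This convention reproduces the familiar worked-example totals
  (86/193 at the optimum, 113/163 and 60 at the fixed cuts). Published
  planning tables round these counts in more than one way; totals can differ
  by a couple of subjects depending on the convention (e.g. the severe-cut
  screening total prints as 370 in some accounts and 372 here, and the
  two-stage prescreening total as 269 here versus up to 272 under coarser
  joint-probability arithmetic). Costs are insensitive to this at the ~1%
  level.
* Two-stage threshold semantics are fixed: `a` always cuts X (second stage),
  `b` always cuts Z (prescreen). Savings are quoted against the one-stage
  optimum re-solved at combined recruitment cost `c_scr + c_pre`, on the
  rounded costs.

## Monte-Carlo verification

Each replicate simulates the full pipeline: draw `(Z, X)` via the
conditional decomposition `Z ~ N`, `X | Z ~ N(mu_x + rho sd_x (Z-mu_z)/sd_z,
sd_x^2 (1-rho^2))`; prescreen, screen, and enroll until the designed total;
randomize 1:1; generate outcomes from the interaction model; analyse with
Welch's two-sample t-test (separate arm variances, Satterthwaite df). A flag
switches to comparing the Welch statistic against the normal critical value,
matching the design-stage approximation; the default is the proper t test,
which at ~40 per arm costs a fraction of a percentage point of power.

Recruitment is `sequential` by default — candidates are drawn until the
enrollment target is met, so prescreen/screen counts (and realized cost) are
random; their expectations follow Wald's identity, `E[M_realized] =
n_total / P(X>=a, Z>=b)`, which slightly exceeds the calculated cost because
enrollment is rounded up. `fixed_sizes` draws exactly the designed prescreen
total instead, making realized enrollment random. Seeding uses one master
seed feeding a `SeedSequence` spawn tree; empirical size is estimated from an
independent stream with `beta1 = beta3 = 0`. Replicates default to 10,000,
giving binomial standard errors of about 0.003 on a power of 0.9.

What the simulator deliberately does not emulate: dropout, noncompliance,
interim looks, non-normal severity or outcome distributions, site- or
volume-dependent screening costs, and covariate-adjusted analysis of the
enrolled sample. Passing simulations therefore validate the design
arithmetic under its own assumptions, not robustness to their violation.

## Worked example defaults

The shipped example (`trialcost.worked_example()`,
`examples/worked_example.yaml`) is a hot-flash severity planning scenario:
severity scored 0–10, `X ~ N(5, 2^2)`, surrogate `Z ~ N(5, 2^2)` with
`rho = 0.7`; `beta0 = 0`, `beta1 = -0.2`, `beta2 = 1`, `beta3 = -0.25`
(solicited by targeting effects at two candidate cuts and solving the 2x2
system — see `solve_betas`), `sigma = 2.5`; unit costs $700 treatment, $700
placebo, $300 recruitment, split $200 screening + $100 prescreening; alpha
0.05, target power 90%. Headline results: one-stage optimum `a = 5.3`
(86 enrolled / 193 screened, $118,100 rounded; continuous objective
$117,453); two-stage optimum X-cut 5.8, Z-cut 5.0 (77/134/269, $107,600),
saving $10,500 or 8.9%.

## Problem sizes

Grid scans evaluate 121 thresholds (one-stage) or 121 x 121 pairs
(two-stage, ~0.15 s). Monte-Carlo checks use 10,000 replicates for operating
characteristics (~15 s) and 10^6-draw sampling oracles for the kernel tests;
these sizes give Monte-Carlo standard errors comfortably below the
tolerances asserted.

## Known limitations

* The normal power approximation is slightly anticonservative versus the
  exact t at small n; the up-rounding of enrollment absorbs this in practice
  (empirical power at the designed sizes stays at or above target in the
  shipped checks).
* Cost units are opaque labels; no discounting or site structure.
* Two screening stages at most; thresholds are fixed up front, not adaptive.
* The marginal analysis discards X after enrollment; a covariate-adjusted
  secondary analysis would be more efficient but is out of scope.
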
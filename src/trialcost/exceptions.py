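"""Exception hierarchy shared across the package."""


class TrialCostError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(TrialCostError, ValueError):
    """A model, cost, or grid parameter violates its invariant."""


class DegenerateTruncationError(TrialCostError, ValueError):
    """Conditioning tail probability too small for stable truncated moments."""


class SingularSolicitationError(TrialCostError, ValueError):
    """The two targeted effects do not identify (beta1, beta3)."""


class UnattainablePowerError(TrialCostError, ValueError):
    """No finite sample size reaches the target power (zero marginal effect)."""


class InfeasiblePointError(TrialCostError, ValueError):
    """A threshold pair leaves essentially nobody eligible."""


class InfeasibleGridError(TrialCostError, ValueError):
    """Every grid point was infeasible for the optimizer."""


class RecruitmentFailureError(TrialCostError, RuntimeError):
    """Sequential recruitment exhausted its candidate budget."""


class ConfigError(TrialCostError, ValueError):
    """A run configuration failed schema or invariant validation."""
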
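import pytest
from hypothesis import settings, HealthCheck

from trialcost import (
    CostStructure,
    GridSpec,
    OutcomeModel,
    ScreeningModel,
    TestSpec,
)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def outcome() -> OutcomeModel:
    """Interaction model of the hot-flash severity planning scenario."""
    return OutcomeModel(beta0=0.0, beta1=-0.2, beta2=1.0, beta3=-0.25, sigma=2.5)


@pytest.fixture(scope="session")
def screening() -> ScreeningModel:
    """X ~ N(5, 2^2), Z ~ N(5, 2^2), correlation 0.7."""
    return ScreeningModel(mu_x=5.0, sd_x=2.0, mu_z=5.0, sd_z=2.0, rho=0.7)


@pytest.fixture(scope="session")
def costs() -> CostStructure:
    """$700 per treated and per placebo subject; $300 recruitment, split
    $200 screening + $100 prescreening in the two-stage procedure."""
    return CostStructure(c_trt=700.0, c_placebo=700.0, c_rec=300.0,
                         c_scr=200.0, c_pre=100.0)


@pytest.fixture(scope="session")
def test_spec() -> TestSpec:
    return TestSpec(alpha=0.05, target_power=0.90, use_z_critical=True)


@pytest.fixture(scope="session")
def grid(screening) -> GridSpec:
    return GridSpec.default_for(screening)
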
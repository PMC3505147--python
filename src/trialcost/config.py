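"""Run configuration: YAML/JSON loading, validation, and the worked example.

A run configuration bundles the outcome model, screening-variable
distribution, unit costs, test specification, threshold grids, and (optional)
simulation settings.  ``load_config`` validates strictly: unknown keys and
missing required keys raise a :class:`ConfigError` naming the offending
fields, and component invariants (positive SDs, |rho| < 1, nonnegative costs,
...) are enforced by the dataclasses themselves.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .effect_model import OutcomeModel, TestSpec
from .exceptions import ConfigError
from .gaussian_tails import ScreeningModel
from .onestage import CostStructure, GridSpec
from .simulate import SimulationSpec

__all__ = ["RunConfig", "load_config", "worked_example"]

_SCHEMA = {
    "outcome": {"beta0", "beta1", "beta2", "beta3", "sigma"},
    "screening": {"mu_x", "sd_x", "mu_z", "sd_z", "rho"},
    "costs": {"c_trt", "c_placebo", "c_rec", "c_scr", "c_pre"},
    "test": {"alpha", "target_power", "use_z_critical"},
    "grid": {"a_lo", "a_hi", "a_step", "b_lo", "b_hi", "b_step", "refine"},
    "sim": {"replicates", "seed", "null_model", "recruitment_mode"},
}
_REQUIRED_SECTIONS = ("outcome", "screening", "costs")
_REQUIRED_FIELDS = {
    "outcome": {"beta0", "beta1", "beta2", "beta3", "sigma"},
    "screening": {"mu_x", "sd_x", "mu_z", "sd_z"},
    "costs": {"c_trt", "c_placebo"},
}


@dataclass(frozen=True)
class RunConfig:
    """Everything a design or simulation run needs, fully validated."""

    outcome: OutcomeModel
    screening: ScreeningModel
    costs: CostStructure
    test: TestSpec
    grid: GridSpec
    sim: SimulationSpec | None = None
    currency: str = "USD"

    def defaults_log(self) -> "list[str]":
        """Human-readable echo of the effective configuration."""
        lines = []
        for name in ("outcome", "screening", "costs", "test", "grid", "sim"):
            obj = getattr(self, name)
            if obj is None:
                lines.append(f"{name}: (none)")
            else:
                fields = ", ".join(
                    f"{f.name}={getattr(obj, f.name)}"
                    for f in dataclasses.fields(obj)
                )
                lines.append(f"{name}: {fields}")
        lines.append(f"currency: {self.currency}")
        return lines


def worked_example(rho: float = 0.7) -> RunConfig:
    """The hot-flash severity planning scenario used throughout the docs.

    Baseline severity X ~ N(5, 2^2) on a 0-10 scale, interaction model with
    beta1 = -0.2, beta2 = 1, beta3 = -0.25, sigma = 2.5; unit costs $700
    treatment, $700 placebo, $300 recruitment (split $200 screening + $100
    prescreening in the two-stage procedure); alpha 0.05, target power 90%.
    """
    screening = ScreeningModel(mu_x=5.0, sd_x=2.0, mu_z=5.0, sd_z=2.0, rho=rho)
    return RunConfig(
        outcome=OutcomeModel(beta0=0.0, beta1=-0.2, beta2=1.0, beta3=-0.25, sigma=2.5),
        screening=screening,
        costs=CostStructure(c_trt=700.0, c_placebo=700.0, c_rec=300.0,
                            c_scr=200.0, c_pre=100.0),
        test=TestSpec(alpha=0.05, target_power=0.90, use_z_critical=True),
        grid=GridSpec.default_for(screening),
    )


def _validate_mapping(raw: dict) -> None:
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = sorted(set(raw) - set(_SCHEMA) - {"currency"})
    if unknown:
        raise ConfigError(f"unknown configuration sections: {unknown}")
    missing = sorted(s for s in _REQUIRED_SECTIONS if s not in raw)
    if missing:
        raise ConfigError(f"missing required configuration sections: {missing}")
    for section, allowed in _SCHEMA.items():
        if section not in raw:
            continue
        if not isinstance(raw[section], dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        bad = sorted(set(raw[section]) - allowed)
        if bad:
            raise ConfigError(f"unknown keys in section {section!r}: {bad}")
        need = sorted(_REQUIRED_FIELDS.get(section, set()) - set(raw[section]))
        if need:
            raise ConfigError(f"missing keys in section {section!r}: {need}")


def load_config(path: "str | Path") -> RunConfig:
    """Parse and validate a YAML (or JSON) run configuration file.

    Omitted optional sections get explicit defaults: test alpha 0.05 / power
    90% / printed critical value, grids mean +/- 3 SD with step 0.1, no
    simulation block.  Retrieve the effective values from
    :meth:`RunConfig.defaults_log`.
    """
    path = Path(path)
    text = path.read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError:
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as err:
            raise ConfigError(f"{path} is neither valid YAML nor JSON: {err}") from err
    _validate_mapping(raw)

    outcome = OutcomeModel(**raw["outcome"])
    screening = ScreeningModel(**raw["screening"])
    costs = CostStructure(**raw["costs"])
    test = TestSpec(**raw.get("test", {}))
    grid = (
        GridSpec(**raw["grid"]) if "grid" in raw else GridSpec.default_for(screening)
    )
    sim = SimulationSpec(**raw["sim"]) if "sim" in raw else None
    return RunConfig(
        outcome=outcome,
        screening=screening,
        costs=costs,
        test=test,
        grid=grid,
        sim=sim,
        currency=str(raw.get("currency", "USD")),
    )
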
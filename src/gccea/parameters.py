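"""Model parameters: point estimates, ranges, strategy definitions, config I/O.

All monetary values are 2012 US$. Each scalar parameter is addressable by a
dotted path (e.g. ``"risk.odds_ratio"``) through :func:`get_param` /
:func:`set_param`, and its deterministic-sensitivity range is recorded in
:data:`PARAM_RANGES` under the same path.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .epidemiology import (
    PopulationWeights,
    RateTable,
    default_population_weights,
    generate_incidence_table,
    generate_life_table,
    read_rate_table,
)

__all__ = [
    "TestCharacteristics",
    "StageDistribution",
    "CostSet",
    "UtilitySet",
    "RiskStratification",
    "SurvivalInputs",
    "EconSettings",
    "StrategySpec",
    "ModelParams",
    "STRATEGY_NAMES",
    "default_strategies",
    "default_params",
    "validate",
    "PARAM_RANGES",
    "get_param",
    "set_param",
    "load_config",
    "write_config",
    "ConfigError",
]

N_STAGES = 4


class ConfigError(ValueError):
    """Raised for malformed or unknown configuration keys/values."""


@dataclass
class TestCharacteristics:
    sensitivity: float = 0.93
    specificity: float = 1.0


@dataclass
class StageDistribution:
    """Proportions of incident cancers by clinical stage 1-4."""

    s1: float
    s2: float
    s3: float
    s4: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.s1, self.s2, self.s3, self.s4)


@dataclass
class CostSet:
    baseline_ogd: float = 350.0
    followup_ogd: float = 340.0
    dx_staging_program: float = 740.0
    dx_staging_usual: float = 1155.0
    treatment_by_stage: tuple[float, ...] = (17000.0, 27200.0, 38000.0, 15500.0)
    post_treatment_followup_annual: float = 955.0
    program_cost_proportion: float = 0.40


@dataclass
class UtilitySet:
    asymptomatic: float = 1.0
    dead: float = 0.0
    stage: tuple[float, ...] = (0.88, 0.86, 0.77, 0.68)


@dataclass
class RiskStratification:
    prevalence: float = 0.135
    odds_ratio: float = 6.0


@dataclass
class SurvivalInputs:
    five_year_survival: tuple[float, ...] = (0.90, 0.70, 0.40, 0.0)
    #: residual 5-year survival substituted for an exact 0 to keep the
    #: constant-hazard conversion finite
    stage4_epsilon: float = 0.001


@dataclass
class EconSettings:
    discount_rate: float = 0.03
    wtp: float = 46200.0
    termination_fraction: float = 0.99
    max_age: int = 110
    half_cycle_correction: bool = False


@dataclass
class StrategySpec:
    """OGD schedule and detection-effect fractions defining one arm.

    ``highrisk_ogd_period`` / ``lowrisk_ogd_period`` are 1 (annual),
    2 (2-yearly) or None (no follow-up OGD for that risk group).
    ``interval_effect_fraction`` is the fraction of the annual-follow-up
    detection effect that persists in the non-OGD years of a 2-yearly
    schedule.
    """

    name: str
    baseline_ogd_all: bool
    highrisk_ogd_period: int | None
    lowrisk_ogd_period: int | None
    interval_effect_fraction: float = 0.0


STRATEGY_NAMES = (
    "none",
    "surveil2y",
    "surveil1y",
    "screen2y",
    "screen2y_plus_surveil1y",
)

#: Human-readable labels used in reports.
STRATEGY_LABELS = {
    "none": "No OGD intervention",
    "surveil2y": "2-yearly surveillance",
    "surveil1y": "Annual surveillance",
    "screen2y": "2-yearly screening",
    "screen2y_plus_surveil1y": "2-yearly screening + annual surveillance",
}


def default_strategies() -> dict[str, StrategySpec]:
    return {
        "none": StrategySpec("none", False, None, None, 0.0),
        "surveil2y": StrategySpec("surveil2y", True, 2, None, 0.60),
        "surveil1y": StrategySpec("surveil1y", True, 1, None, 0.0),
        "screen2y": StrategySpec("screen2y", True, 2, 2, 0.40),
        "screen2y_plus_surveil1y": StrategySpec(
            "screen2y_plus_surveil1y", True, 1, 2, 0.40
        ),
    }


@dataclass
class ModelParams:
    test: TestCharacteristics = field(default_factory=TestCharacteristics)
    stage_program: StageDistribution = field(
        default_factory=lambda: StageDistribution(0.85, 0.04, 0.08, 0.03)
    )
    stage_usual: StageDistribution = field(
        default_factory=lambda: StageDistribution(0.07, 0.17, 0.33, 0.43)
    )
    costs: CostSet = field(default_factory=CostSet)
    utilities: UtilitySet = field(default_factory=UtilitySet)
    risk: RiskStratification = field(default_factory=RiskStratification)
    survival: SurvivalInputs = field(default_factory=SurvivalInputs)
    econ: EconSettings = field(default_factory=EconSettings)
    strategies: dict[str, StrategySpec] = field(default_factory=default_strategies)
    mortality: RateTable | None = None
    incidence: RateTable | None = None
    weights: PopulationWeights | None = None
    seed: int = 0

    def copy(self) -> "ModelParams":
        return copy.deepcopy(self)


def default_params() -> ModelParams:
    """Point estimates with synthetic epidemiology attached."""
    mortality = generate_life_table("male").update(generate_life_table("female"))
    incidence = generate_incidence_table("male").update(
        generate_incidence_table("female")
    )
    return ModelParams(
        mortality=mortality,
        incidence=incidence,
        weights=default_population_weights(),
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _check_unit(name: str, value: float, problems: list[str], lo=0.0, hi=1.0) -> None:
    if not lo <= value <= hi:
        problems.append(f"{name}: {value} outside [{lo}, {hi}]")


def validate(params: ModelParams) -> list[str]:
    """Return a list of invariant violations; empty when all hold."""
    p: list[str] = []
    _check_unit("test.sensitivity", params.test.sensitivity, p)
    _check_unit("test.specificity", params.test.specificity, p)
    for label, dist in (
        ("stage_program", params.stage_program),
        ("stage_usual", params.stage_usual),
    ):
        t = dist.as_tuple()
        if any(x < 0 for x in t):
            p.append(f"{label}: negative proportion")
        if abs(sum(t) - 1.0) > 1e-12:
            p.append(f"{label}: proportions sum to {sum(t)!r}, not 1")
    c = params.costs
    for name in (
        "baseline_ogd",
        "followup_ogd",
        "dx_staging_program",
        "dx_staging_usual",
        "post_treatment_followup_annual",
    ):
        if getattr(c, name) < 0:
            p.append(f"costs.{name}: negative")
    if any(x < 0 for x in c.treatment_by_stage):
        p.append("costs.treatment_by_stage: negative")
    if not 0.0 <= c.program_cost_proportion < 1.0:
        p.append(
            f"costs.program_cost_proportion: {c.program_cost_proportion}"
            " outside [0, 1)"
        )
    u = params.utilities
    _check_unit("utilities.asymptomatic", u.asymptomatic, p)
    _check_unit("utilities.dead", u.dead, p)
    for i, x in enumerate(u.stage, start=1):
        _check_unit(f"utilities.stage{i}", x, p)
    if any(a < b for a, b in zip(u.stage, u.stage[1:])):
        p.append("utilities.stage: not non-increasing with stage")
    r = params.risk
    if not 0.0 < r.prevalence < 1.0:
        p.append(f"risk.prevalence: {r.prevalence} outside (0, 1)")
    if r.odds_ratio < 1.0:
        p.append(f"risk.odds_ratio: {r.odds_ratio} < 1")
    s = params.survival
    for i, x in enumerate(s.five_year_survival, start=1):
        _check_unit(f"survival.stage{i}", x, p)
    if any(a < b for a, b in zip(s.five_year_survival, s.five_year_survival[1:])):
        p.append("survival.five_year_survival: not non-increasing with stage")
    if not 0.0 < s.stage4_epsilon <= 1.0:
        p.append(f"survival.stage4_epsilon: {s.stage4_epsilon} outside (0, 1]")
    e = params.econ
    if e.discount_rate < 0:
        p.append(f"econ.discount_rate: {e.discount_rate} < 0")
    if e.wtp <= 0:
        p.append(f"econ.wtp: {e.wtp} <= 0")
    if not 0.0 < e.termination_fraction <= 1.0:
        p.append("econ.termination_fraction outside (0, 1]")
    for spec in params.strategies.values():
        if not 0.0 <= spec.interval_effect_fraction <= 1.0:
            p.append(f"strategies.{spec.name}.interval_effect_fraction outside [0,1]")
        for attr in ("highrisk_ogd_period", "lowrisk_ogd_period"):
            period = getattr(spec, attr)
            if period not in (None, 1, 2):
                p.append(f"strategies.{spec.name}.{attr}: {period} not in {{1,2,none}}")
    for table, label in ((params.mortality, "mortality"), (params.incidence, "incidence")):
        if table is None:
            p.append(f"{label} table missing")
        else:
            p.extend(f"{label}: {msg}" for msg in table.validate())
    if params.weights is None:
        p.append("population weights missing")
    return p


# ---------------------------------------------------------------------------
# Dotted-path access and DSA ranges
# ---------------------------------------------------------------------------

#: path -> attribute chain; integer elements index into tuples.
_PATHS: dict[str, tuple] = {
    "test.sensitivity": ("test", "sensitivity"),
    "test.specificity": ("test", "specificity"),
    "risk.prevalence": ("risk", "prevalence"),
    "risk.odds_ratio": ("risk", "odds_ratio"),
    "costs.baseline_ogd": ("costs", "baseline_ogd"),
    "costs.followup_ogd": ("costs", "followup_ogd"),
    "costs.dx_staging_program": ("costs", "dx_staging_program"),
    "costs.dx_staging_usual": ("costs", "dx_staging_usual"),
    "costs.treatment_stage1": ("costs", "treatment_by_stage", 0),
    "costs.treatment_stage2": ("costs", "treatment_by_stage", 1),
    "costs.treatment_stage3": ("costs", "treatment_by_stage", 2),
    "costs.treatment_stage4": ("costs", "treatment_by_stage", 3),
    "costs.post_treatment_followup_annual": (
        "costs",
        "post_treatment_followup_annual",
    ),
    "costs.program_cost_proportion": ("costs", "program_cost_proportion"),
    "utilities.stage1": ("utilities", "stage", 0),
    "utilities.stage2": ("utilities", "stage", 1),
    "utilities.stage3": ("utilities", "stage", 2),
    "utilities.stage4": ("utilities", "stage", 3),
    "econ.discount_rate": ("econ", "discount_rate"),
    "econ.wtp": ("econ", "wtp"),
    "strategies.surveil2y.interval_effect_fraction": (
        "strategies",
        "surveil2y",
        "interval_effect_fraction",
    ),
    "strategies.screen2y.interval_effect_fraction": (
        "strategies",
        "screen2y",
        "interval_effect_fraction",
    ),
}

#: Deterministic-sensitivity ranges. Clinical parameters use literature
#: bounds; cost parameters are halved/doubled around the base case (stage-4
#: treatment and follow-up costs carry their published asymmetric bounds).
#: ``start_age`` is handled specially by the sensitivity module.
PARAM_RANGES: dict[str, tuple[float, float]] = {
    "test.sensitivity": (0.44, 0.99),
    "test.specificity": (0.95, 1.0),
    "risk.prevalence": (0.065, 0.27),
    "risk.odds_ratio": (2.4, 21.5),
    "costs.baseline_ogd": (175.0, 750.0),
    "costs.followup_ogd": (170.0, 680.0),
    "costs.dx_staging_program": (660.0, 820.0),
    "costs.dx_staging_usual": (960.0, 1440.0),
    "costs.treatment_stage1": (8500.0, 34000.0),
    "costs.treatment_stage2": (13600.0, 54400.0),
    "costs.treatment_stage3": (19000.0, 76000.0),
    "costs.treatment_stage4": (7800.0, 31100.0),
    "costs.post_treatment_followup_annual": (900.0, 1300.0),
    "costs.program_cost_proportion": (0.20, 0.80),
    "utilities.stage1": (0.60, 1.00),
    "utilities.stage2": (0.62, 0.99),
    "utilities.stage3": (0.58, 0.95),
    "utilities.stage4": (0.51, 0.84),
    "econ.discount_rate": (0.0, 0.05),
    "econ.wtp": (15000.0, 100000.0),
    "strategies.surveil2y.interval_effect_fraction": (0.40, 0.90),
    "start_age": (50, 69),
}


def _walk(params: ModelParams, chain: tuple):
    obj = params
    for step in chain[:-1]:
        obj = obj[step] if isinstance(obj, dict) else getattr(obj, step)
    return obj, chain[-1]


def get_param(params: ModelParams, path: str) -> float:
    if path not in _PATHS:
        raise KeyError(f"unknown parameter path {path!r}")
    obj, last = _walk(params, _PATHS[path])
    if isinstance(last, int):
        return obj[last]
    return getattr(obj, last)


def set_param(params: ModelParams, path: str, value: float) -> ModelParams:
    """Return a deep copy of ``params`` with the addressed field replaced."""
    if path not in _PATHS:
        raise KeyError(f"unknown parameter path {path!r}")
    out = params.copy()
    chain = _PATHS[path]
    obj, last = _walk(out, chain)
    if isinstance(last, int):
        # tuple-valued field: chain[-2] names the tuple attribute on obj's
        # parent, so re-walk one level up
        parent, attr = _walk(out, chain[:-1])
        tup = list(getattr(parent, attr))
        tup[last] = value
        setattr(parent, attr, tuple(tup))
    else:
        setattr(obj, last, value)
    return out


# ---------------------------------------------------------------------------
# Config I/O (YAML)
# ---------------------------------------------------------------------------

_SCALAR_SECTIONS = {
    "test": ("sensitivity", "specificity"),
    "stage_program": ("s1", "s2", "s3", "s4"),
    "stage_usual": ("s1", "s2", "s3", "s4"),
    "costs": (
        "baseline_ogd",
        "followup_ogd",
        "dx_staging_program",
        "dx_staging_usual",
        "post_treatment_followup_annual",
        "program_cost_proportion",
    ),
    "utilities": ("asymptomatic", "dead"),
    "risk": ("prevalence", "odds_ratio"),
    "survival": ("stage4_epsilon",),
    "econ": (
        "discount_rate",
        "wtp",
        "termination_fraction",
        "max_age",
        "half_cycle_correction",
    ),
}

_TUPLE_FIELDS = {
    ("costs", "treatment_by_stage"): 4,
    ("utilities", "stage"): 4,
    ("survival", "five_year_survival"): 4,
}

_STRATEGY_FIELDS = (
    "baseline_ogd_all",
    "highrisk_ogd_period",
    "lowrisk_ogd_period",
    "interval_effect_fraction",
)


def _apply_section(obj, section: str, data: dict) -> None:
    if not isinstance(data, dict):
        raise ConfigError(f"{section}: expected a mapping")
    allowed = set(_SCALAR_SECTIONS.get(section, ()))
    tuple_fields = {f for (s, f) in _TUPLE_FIELDS if s == section}
    for key, value in data.items():
        if key in tuple_fields:
            n = _TUPLE_FIELDS[(section, key)]
            if not isinstance(value, (list, tuple)) or len(value) != n:
                raise ConfigError(f"{section}.{key}: expected a list of {n} numbers")
            setattr(obj, key, tuple(float(v) for v in value))
        elif key in allowed:
            current = getattr(obj, key)
            if isinstance(current, bool):
                if not isinstance(value, bool):
                    raise ConfigError(f"{section}.{key}: expected a boolean")
                setattr(obj, key, value)
            elif isinstance(current, int) and not isinstance(current, bool):
                setattr(obj, key, int(value))
            else:
                if not isinstance(value, (int, float)):
                    raise ConfigError(f"{section}.{key}: expected a number")
                setattr(obj, key, float(value))
        else:
            raise ConfigError(f"unknown config key: {section}.{key}")


def apply_config_dict(params: ModelParams, data: dict) -> ModelParams:
    out = params.copy()
    if data is None:
        return out
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    for section, payload in data.items():
        if section in _SCALAR_SECTIONS:
            _apply_section(getattr(out, section), section, payload)
        elif section == "strategies":
            if not isinstance(payload, dict):
                raise ConfigError("strategies: expected a mapping")
            for name, fields in payload.items():
                if name not in out.strategies:
                    raise ConfigError(f"unknown config key: strategies.{name}")
                if not isinstance(fields, dict):
                    raise ConfigError(f"strategies.{name}: expected a mapping")
                for key, value in fields.items():
                    if key not in _STRATEGY_FIELDS:
                        raise ConfigError(
                            f"unknown config key: strategies.{name}.{key}"
                        )
                    setattr(out.strategies[name], key, value)
        elif section == "epidemiology":
            if not isinstance(payload, dict):
                raise ConfigError("epidemiology: expected a mapping")
            for key, value in payload.items():
                if key == "mortality_csv":
                    out.mortality = read_rate_table(value, "mortality")
                elif key == "incidence_csv":
                    out.incidence = read_rate_table(value, "incidence")
                else:
                    raise ConfigError(f"unknown config key: epidemiology.{key}")
        elif section == "seed":
            out.seed = int(payload)
        else:
            raise ConfigError(f"unknown config key: {section}")
    return out


def load_config(path: str | Path) -> ModelParams:
    """Defaults overridden by the YAML config at ``path``."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    params = apply_config_dict(default_params(), data)
    problems = validate(params)
    if problems:
        raise ConfigError("invalid configuration: " + "; ".join(problems))
    return params


def to_config_dict(params: ModelParams) -> dict:
    """Scalar parameters as a nested dict (the full config schema)."""
    out: dict = {}
    for section, fields in _SCALAR_SECTIONS.items():
        obj = getattr(params, section)
        out[section] = {f: getattr(obj, f) for f in fields}
    for (section, f), _n in _TUPLE_FIELDS.items():
        out[section][f] = list(getattr(getattr(params, section), f))
    out["strategies"] = {
        name: {f: getattr(spec, f) for f in _STRATEGY_FIELDS}
        for name, spec in params.strategies.items()
    }
    out["seed"] = params.seed
    return out


def write_config(params: ModelParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_config_dict(params), fh, sort_keys=False)
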
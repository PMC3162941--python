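"""Engine configuration: schema, validation, YAML round-trip, defaults.

The configuration is one human-editable YAML document so that clinicians can
review the rule base without reading code. The shipped default
(``data/default_config.yaml``) encodes the specialist-elicited membership
breakpoints and the six-rule base with their alert messages and urgencies.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .engine import FuzzyEngine, Rule, Urgency
from .membership import FuzzySet, LinguisticVariable

__all__ = [
    "EngineConfig",
    "load_config",
    "save_config",
    "default_config",
    "build_engine",
]


class FuzzySetConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    points: list[tuple[float, float]] = Field(min_length=2)

    @field_validator("points")
    @classmethod
    def _points_valid(cls, pts: list[tuple[float, float]]) -> list[tuple[float, float]]:
        xs = [x for x, _ in pts]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError("breakpoint x values must be strictly increasing")
        if any(not 0.0 <= mu <= 1.0 for _, mu in pts):
            raise ValueError("membership degrees must lie in [0, 1]")
        return pts


class VariableConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    units: str
    domain: tuple[float, float]
    sets: list[FuzzySetConfig] = Field(min_length=1)

    @model_validator(mode="after")
    def _check(self) -> "VariableConfig":
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError(f"variable {self.name!r}: domain lo must be < hi")
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            raise ValueError(f"variable {self.name!r}: duplicate set names")
        return self


class RuleConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    id: int
    antecedents: dict[str, str] = Field(alias="if")
    consequent: str = Field(alias="then")
    message: str
    urgency: Literal["none", "low", "medium", "high"]


class MonitoringConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    debounce_seconds: float = 0.0
    stale_gap_seconds: float = 30.0

    @model_validator(mode="after")
    def _check(self) -> "MonitoringConfig":
        if self.debounce_seconds < 0 or self.stale_gap_seconds <= 0:
            raise ValueError("monitoring windows must be non-negative / positive")
        return self


class EngineConfig(BaseModel):
    """Full engine + monitoring configuration; round-trips losslessly."""

    model_config = ConfigDict(extra="forbid")

    variables: list[VariableConfig] = Field(min_length=1)
    output: VariableConfig
    rules: list[RuleConfig] = Field(min_length=1)
    monitoring: MonitoringConfig = Field(default_factory=MonitoringConfig)

    @model_validator(mode="after")
    def _cross_references(self) -> "EngineConfig":
        terms = {v.name: {s.name for s in v.sets} for v in self.variables}
        out_terms = {s.name for s in self.output.sets}
        ids = [r.id for r in self.rules]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate rule ids")
        for rule in self.rules:
            for var, term in rule.antecedents.items():
                if var not in terms:
                    raise ValueError(f"rule {rule.id}: unknown variable {var!r}")
                if term not in terms[var]:
                    raise ValueError(
                        f"rule {rule.id}: variable {var!r} has no term {term!r}"
                    )
            if rule.consequent not in out_terms:
                raise ValueError(f"rule {rule.id}: unknown output term {rule.consequent!r}")
        return self


def load_config(path: str | Path) -> EngineConfig:
    """Load and validate a YAML engine configuration."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValueError(f"{path}: YAML parse failure: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return EngineConfig.model_validate(raw)


def save_config(config: EngineConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (inverse of :func:`load_config`)."""
    raw = config.model_dump(by_alias=True, mode="json")
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def default_config() -> EngineConfig:
    """The shipped configuration with the published breakpoints and rules."""
    text = resources.files("fuzzyvitals.data").joinpath("default_config.yaml").read_text()
    return EngineConfig.model_validate(yaml.safe_load(text))


def _to_variable(cfg: VariableConfig) -> LinguisticVariable:
    return LinguisticVariable(
        name=cfg.name,
        units=cfg.units,
        domain=cfg.domain,
        sets=tuple(FuzzySet(s.name, tuple(s.points)) for s in cfg.sets),
    )


def build_engine(config: EngineConfig | None = None) -> FuzzyEngine:
    """Instantiate a :class:`FuzzyEngine` from a validated configuration."""
    cfg = config if config is not None else default_config()
    variables = [_to_variable(v) for v in cfg.variables]
    output = _to_variable(cfg.output)
    rules = [
        Rule(
            id=r.id,
            antecedents=tuple(r.antecedents.items()),
            consequent=r.consequent,
            message=r.message,
            urgency=Urgency[r.urgency],
        )
        for r in cfg.rules
    ]
    return FuzzyEngine(variables, output, rules)
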
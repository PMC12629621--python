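"""Charlson Comorbidity Index (CCI) scoring and the screening gates.

The pipeline estimates whether a patient can expect to live at least ten
more years before any PSA-testing recommendation is made. The estimate is
the classic Charlson transform

    P(10-year survival) = 0.983 ** exp(0.9 * score)

where ``score`` is the age-adjusted CCI: a weighted sum over coded
comorbidities (original 1/2/3/6 weight tiers) plus one point per decade of
age from 50. Two hard gates follow:

* **age gate** — men aged over the configured limit (default 72) do not
  proceed to screening recommendations;
* **life-expectancy gate** — men whose estimated 10-year survival falls
  below the configured threshold (default 0.50, i.e. not *expected* to
  survive ten years) do not proceed.

Both gates, the weight table, the severity hierarchy and the age bands are
configuration (``data/cci_config.yaml``), so an alternative comorbidity
calculator can be substituted — or the gate disabled outright — without
code changes.
"""
from __future__ import annotations

import math
from enum import Enum
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .cases import CaseScenario
from .errors import ConfigurationError

SURVIVAL_BASE = 0.983
SURVIVAL_RATE = 0.9


class CCIConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    weights: dict[str, int]
    severity_hierarchy: tuple[tuple[str, str], ...] = ()
    age_bands: tuple[dict, ...] = ()


class GateConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    enabled: bool = True
    age_limit: int = 72
    survival_threshold: float = Field(default=0.50, ge=0.0, le=1.0)


class CCIResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    comorbidity_points: int = Field(ge=0)
    age_points: int = Field(ge=0)
    score: int
    ten_year_survival: float = Field(ge=0.0, le=1.0)
    itemized: tuple[tuple[str, int], ...] = ()

    @model_validator(mode="after")
    def _consistent(self) -> "CCIResult":
        if self.score != self.comorbidity_points + self.age_points:
            raise ValueError("score must equal comorbidity_points + age_points")
        if sum(w for _, w in self.itemized) != self.comorbidity_points:
            raise ValueError("itemized weights must sum to comorbidity_points")
        return self


class GateReason(str, Enum):
    age_over_limit = "age_over_limit"
    life_expectancy_under_10y = "life_expectancy_under_10y"


class GateDecision(BaseModel):
    model_config = ConfigDict(frozen=True)

    eligible: bool
    reasons: tuple[GateReason, ...] = ()
    age_limit_used: int
    survival_threshold_used: float

    @model_validator(mode="after")
    def _consistent(self) -> "GateDecision":
        if self.eligible != (len(self.reasons) == 0):
            raise ValueError("eligible must be false iff reasons non-empty")
        return self


def _data_path(name: str) -> Path:
    return Path(str(resources.files("psaguide").joinpath("data", name)))


@lru_cache(maxsize=4)
def load_cci_config(path: Optional[str] = None) -> CCIConfig:
    raw = yaml.safe_load(Path(path or _data_path("cci_config.yaml")).read_text())
    return CCIConfig(
        weights=raw["weights"],
        severity_hierarchy=tuple(tuple(p) for p in raw.get("severity_hierarchy", [])),
        age_bands=tuple(raw.get("age_bands", [])),
    )


@lru_cache(maxsize=4)
def load_gate_config(path: Optional[str] = None) -> GateConfig:
    raw = yaml.safe_load(Path(path or _data_path("cci_config.yaml")).read_text())
    return GateConfig(**raw.get("gate", {}))


def age_points(age: int, config: Optional[CCIConfig] = None) -> int:
    config = config or load_cci_config()
    for band in config.age_bands:
        if band["min_age"] <= age <= band["max_age"]:
            return int(band["points"])
    return 0


def cci_score(case: CaseScenario, config: Optional[CCIConfig] = None) -> CCIResult:
    """Age-adjusted CCI for a case.

    Each condition counts once; when both the mild and severe form of the
    same organ system are coded, only the severe weight counts.
    """
    config = config or load_cci_config()
    present = set(case.comorbidities)
    missing = present - set(config.weights)
    if missing:
        raise ConfigurationError(
            f"conditions absent from the weight table: {sorted(missing)}"
        )
    for mild, severe in config.severity_hierarchy:
        if mild in present and severe in present:
            present.discard(mild)
    itemized = tuple(sorted((c, config.weights[c]) for c in present))
    comorbidity_points = sum(w for _, w in itemized)
    ap = age_points(case.age, config)
    score = comorbidity_points + ap
    return CCIResult(
        comorbidity_points=comorbidity_points,
        age_points=ap,
        score=score,
        ten_year_survival=ten_year_survival(score),
        itemized=itemized,
    )


def ten_year_survival(score: int) -> float:
    """Estimated 10-year survival, ``0.983 ** exp(0.9 * score)``, in [0, 1]."""
    if score < 0:
        raise ValueError(f"CCI score must be non-negative, got {score}")
    p = SURVIVAL_BASE ** math.exp(SURVIVAL_RATE * score)
    return min(1.0, max(0.0, p))


def screening_gate(
    case: CaseScenario,
    cci: CCIResult,
    config: Optional[GateConfig] = None,
) -> GateDecision:
    """Apply the age and life-expectancy gates.

    Pure function of (case, cci, config): the age gate is evaluated first,
    then the survival gate; both reasons are reported when both fail. With
    ``enabled=False`` every case is eligible (gate bypass at the clinician's
    discretion).
    """
    config = config or load_gate_config()
    reasons: list[GateReason] = []
    if config.enabled:
        if case.age > config.age_limit:
            reasons.append(GateReason.age_over_limit)
        if cci.ten_year_survival < config.survival_threshold:
            reasons.append(GateReason.life_expectancy_under_10y)
    return GateDecision(
        eligible=not reasons,
        reasons=tuple(reasons),
        age_limit_used=config.age_limit,
        survival_threshold_used=config.survival_threshold,
    )
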
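"""Deterministic, config-driven EAU/AUA PSA-testing rule engine.

Encodes the two societies' PSA-testing rules as data (``data/rules.yaml``)
interpreted by a small fixed-priority evaluator, and the reconciliation
step that combines the per-guideline answers into a final recommendation.
Because the two guidelines occasionally disagree (e.g. follow-up intervals
of exactly 2 years vs 2-4 years), separate recommendations are produced
from each rule set and then reconciled: concordant pairs merge into a
single final action (interval intersection), discordant pairs are both
presented, each labelled by source.

Rule priority, highest first:

1. gate refusal (a gate-ineligible man receives ``no_testing`` from both
   guidelines, regardless of PSA);
2. special findings — abnormal DRE (refer even with normal PSA), active
   UTI with elevated PSA (treat, then repeat);
3. elevated PSA workup — markedly elevated (> 10 ng/mL) or confirmed
   elevation refer to urology; a first moderate elevation (3-10 ng/mL)
   triggers a confirmatory repeat after a few weeks, **never** a value
   below the 3.0 ng/mL threshold;
4. age-band screening/follow-up rules with per-guideline intervals.

Every recommendation carries the identifiers of the rules that fired, for
explainability and for the pipeline's constrain-to-context audit.
"""
from __future__ import annotations

import json
from enum import Enum
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .cases import CaseScenario, DREStatus, latest_psa
from .cci import GateDecision


class Action(str, Enum):
    no_testing = "no_testing"
    offer_psa_now = "offer_psa_now"
    routine_interval = "routine_interval"
    confirmatory_repeat_weeks = "confirmatory_repeat_weeks"
    refer_urology = "refer_urology"
    defer_treat_uti_then_repeat = "defer_treat_uti_then_repeat"


class Source(str, Enum):
    EAU = "EAU"
    AUA = "AUA"
    COMBINED = "combined"


class Recommendation(BaseModel):
    model_config = ConfigDict(frozen=True)

    source: Source
    action: Action
    interval_months: Optional[tuple[int, int]] = None
    shared_decision: bool = False
    rationale: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _consistent(self) -> "Recommendation":
        if (self.interval_months is not None) != (self.action is Action.routine_interval):
            raise ValueError("interval_months present iff action is routine_interval")
        if self.interval_months is not None and self.interval_months[0] > self.interval_months[1]:
            raise ValueError("interval lower bound exceeds upper bound")
        if self.action is not Action.no_testing and not self.rationale:
            raise ValueError("rationale required for any action other than no_testing")
        return self


class DualRecommendation(BaseModel):
    model_config = ConfigDict(frozen=True)

    eau: Recommendation
    aua: Recommendation
    concordant: bool
    final_actions: tuple[Recommendation, ...]

    @model_validator(mode="after")
    def _consistent(self) -> "DualRecommendation":
        if len(self.final_actions) != (1 if self.concordant else 2):
            raise ValueError("final_actions length must be 1 when concordant, 2 otherwise")
        return self


class GuidelineParams(BaseModel):
    model_config = ConfigDict(frozen=True)

    screening_age_min: int
    screening_age_max: int
    routine_interval_months: tuple[int, int]
    risk_adapted_start: dict[str, int] = {}
    shared_decision_age: int = 50


class RuleConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    version: int = 1
    psa_elevated_threshold: float = 3.0
    psa_moderate_upper: float = 10.0
    eau: GuidelineParams
    aua: GuidelineParams
    uti_defer: bool = True
    abnormal_dre_refer: bool = True


@lru_cache(maxsize=4)
def load_rules(path: Optional[str] = None) -> RuleConfig:
    if path is None:
        path = str(resources.files("psaguide").joinpath("data", "rules.yaml"))
    raw = yaml.safe_load(Path(path).read_text())
    shared = raw.get("shared", {})
    special = raw.get("special_rules", {})
    return RuleConfig(
        version=raw.get("version", 1),
        psa_elevated_threshold=shared.get("psa_elevated_threshold", 3.0),
        psa_moderate_upper=shared.get("psa_moderate_upper", 10.0),
        eau=GuidelineParams(**raw["eau"]),
        aua=GuidelineParams(**raw["aua"]),
        uti_defer=special.get("uti_defer", True),
        abnormal_dre_refer=special.get("abnormal_dre_refer", True),
    )


def default_rules() -> RuleConfig:
    return load_rules()


def _risk_adjusted_start(case: CaseScenario, params: GuidelineParams) -> int:
    start = params.screening_age_min
    for rf in case.risk_factors:
        start = min(start, params.risk_adapted_start.get(rf.value, start))
    return start


def _elevated_count(case: CaseScenario, threshold: float) -> int:
    return sum(1 for r in case.psa_history if r.value >= threshold)


def _base_recommendation(
    case: CaseScenario,
    gate: GateDecision,
    rules: RuleConfig,
    source: Source,
) -> Recommendation:
    """Age/PSA rules for one guideline, before special-case overrides."""
    tag = source.value.lower()
    params = rules.eau if source is Source.EAU else rules.aua
    if not gate.eligible:
        return Recommendation(
            source=source, action=Action.no_testing, rationale=("gate.ineligible",)
        )
    latest = latest_psa(case)
    if latest is not None and latest.value >= rules.psa_elevated_threshold:
        if latest.value > rules.psa_moderate_upper:
            return Recommendation(
                source=source,
                action=Action.refer_urology,
                rationale=(f"{tag}.psa_markedly_elevated_refer",),
            )
        if _elevated_count(case, rules.psa_elevated_threshold) >= 2:
            return Recommendation(
                source=source,
                action=Action.refer_urology,
                rationale=(f"{tag}.psa_confirmed_elevated_refer",),
            )
        return Recommendation(
            source=source,
            action=Action.confirmatory_repeat_weeks,
            rationale=(f"{tag}.psa_confirmatory_repeat",),
        )
    start = _risk_adjusted_start(case, params)
    shared = case.age >= params.shared_decision_age
    if case.age < start:
        return Recommendation(
            source=source,
            action=Action.no_testing,
            shared_decision=True,
            rationale=(f"{tag}.below_screening_age",),
        )
    if case.age > params.screening_age_max:
        return Recommendation(
            source=source,
            action=Action.no_testing,
            shared_decision=True,
            rationale=(f"{tag}.beyond_screening_band",),
        )
    if latest is None:
        if source is Source.EAU:
            return Recommendation(
                source=source,
                action=Action.offer_psa_now,
                shared_decision=shared,
                rationale=("eau.offer_baseline_psa",),
            )
        return Recommendation(
            source=source,
            action=Action.routine_interval,
            interval_months=params.routine_interval_months,
            shared_decision=shared,
            rationale=("aua.routine_screening_band",),
        )
    return Recommendation(
        source=source,
        action=Action.routine_interval,
        interval_months=params.routine_interval_months,
        shared_decision=shared,
        rationale=(f"{tag}.normal_psa_routine_interval",),
    )


def apply_special_rules(
    case: CaseScenario,
    base: Recommendation,
    rules: Optional[RuleConfig] = None,
) -> Recommendation:
    """Special-case overrides on top of the age/PSA base recommendation.

    Gate refusals pass through untouched (a gate-ineligible man with an
    elevated PSA still receives ``no_testing``: further testing brings no
    benefit). Then, in priority order: abnormal DRE overrides to a urology
    referral even with a normal PSA; an elevated PSA during an active UTI
    is likely spurious and overrides a confirmatory repeat with
    treat-the-infection-then-repeat.
    """
    rules = rules or default_rules()
    if base.action is Action.no_testing and "gate.ineligible" in base.rationale:
        return base
    if rules.abnormal_dre_refer and case.dre is DREStatus.abnormal:
        return Recommendation(
            source=base.source,
            action=Action.refer_urology,
            rationale=("special.abnormal_dre_refer",),
        )
    latest = latest_psa(case)
    if (
        rules.uti_defer
        and case.active_uti
        and latest is not None
        and latest.value >= rules.psa_elevated_threshold
    ):
        return Recommendation(
            source=base.source,
            action=Action.defer_treat_uti_then_repeat,
            rationale=("special.uti_spurious_elevation_defer",),
        )
    return base


def recommend_eau(
    case: CaseScenario, gate: GateDecision, rules: Optional[RuleConfig] = None
) -> Recommendation:
    rules = rules or default_rules()
    return apply_special_rules(case, _base_recommendation(case, gate, rules, Source.EAU), rules)


def recommend_aua(
    case: CaseScenario, gate: GateDecision, rules: Optional[RuleConfig] = None
) -> Recommendation:
    rules = rules or default_rules()
    return apply_special_rules(case, _base_recommendation(case, gate, rules, Source.AUA), rules)


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def reconcile(eau: Recommendation, aua: Recommendation) -> DualRecommendation:
    """Combine the per-guideline answers into the final recommendation.

    Concordant (same action; overlapping intervals when both are interval
    recommendations) pairs merge into one final action carrying the
    interval intersection; discordant pairs are both retained, each
    labelled by source. Intersection is conservative and order-independent.
    """
    concordant = eau.action == aua.action
    interval: Optional[tuple[int, int]] = None
    if concordant and eau.action is Action.routine_interval:
        assert eau.interval_months is not None and aua.interval_months is not None
        if _intervals_overlap(eau.interval_months, aua.interval_months):
            interval = (
                max(eau.interval_months[0], aua.interval_months[0]),
                min(eau.interval_months[1], aua.interval_months[1]),
            )
        else:
            concordant = False
    if concordant:
        rationale = eau.rationale + tuple(r for r in aua.rationale if r not in eau.rationale)
        merged = Recommendation(
            source=Source.COMBINED,
            action=eau.action,
            interval_months=interval,
            shared_decision=eau.shared_decision or aua.shared_decision,
            rationale=rationale,
        )
        return DualRecommendation(eau=eau, aua=aua, concordant=True, final_actions=(merged,))
    return DualRecommendation(eau=eau, aua=aua, concordant=False, final_actions=(eau, aua))


def recommend_dual(
    case: CaseScenario, gate: GateDecision, rules: Optional[RuleConfig] = None
) -> DualRecommendation:
    """Convenience: per-guideline recommendations reconciled in one call."""
    rules = rules or default_rules()
    return reconcile(recommend_eau(case, gate, rules), recommend_aua(case, gate, rules))


def dual_to_json(dual: DualRecommendation) -> str:
    """Canonical, hash-stable JSON serialization."""
    return json.dumps(dual.model_dump(mode="json"), sort_keys=True)
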
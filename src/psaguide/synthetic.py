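"""Synthetic gold-labelled case cohorts.

The study's 44 vignettes are unpublished, so this module generates
cohorts with the same category structure — default counts 11/9/9/8/7
across the five categories, i.e. 20 screening and 24 follow-up cases —
and gold labels derived by running the rule engine on each case (gold is
self-consistent by construction, so the mock pipeline's accuracy on a
generated cohort is exactly 100% and any deviation is attributable to the
component under test).

Per-category designs:

* **cat1** (screening recommended): men 50-69, light comorbidity burden
  keeping estimated 10-year survival above the gate threshold, no PSA
  history; a minority carry risk factors or request screening.
* **cat2** (screening not recommended): alternating age-gate failures
  (73-85) and life-expectancy failures (55-72 with heavy burden, e.g.
  metastatic disease).
* **cat3** (normal PSA follow-up): men 50-69 with a latest PSA below
  3.0 ng/mL.
* **cat4** (elevated PSA): first unconfirmed moderate elevations
  (3-10 ng/mL), confirmed elevations (two readings >= 3.0), and marked
  elevations (> 10 ng/mL), in a fixed 4/2/2 split of the default 8.
* **cat5** (others): UTI-spurious elevations, elevated PSA with
  prohibitive comorbidity (gate-ineligible), and abnormal DRE with normal
  PSA, split 3/2/2 by default.

All randomness flows from one seed through per-category
``numpy.random.SeedSequence`` children, so cohorts are bit-reproducible.
Simulated clinician arms for harness testing come from
:func:`degrade_ratings`, which flips engine-correct ratings into the four
error subtypes at configurable per-category rates.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .cases import CaseScenario, Category, DREStatus, Preference, RiskFactor, parse_case
from .cci import CCIConfig, GateConfig, cci_score, screening_gate
from .engine import Action, RuleConfig, default_rules, recommend_dual
from .errors import GenerationError
from .evaluation import Arm, ErrorType, GoldLabel, GradedRating, gold_from_engine

DEFAULT_COUNTS = {
    Category.cat1_screen_recommended: 11,
    Category.cat2_screen_not_recommended: 9,
    Category.cat3_normal_followup: 9,
    Category.cat4_elevated_psa: 8,
    Category.cat5_other: 7,
}

_LIGHT_COMORBIDITIES = (
    "diabetes_uncomplicated",
    "chronic_pulmonary_disease",
    "peptic_ulcer_disease",
    "mild_liver_disease",
    "peripheral_vascular_disease",
)
_HEAVY_COMORBIDITIES = (
    ("metastatic_solid_tumor",),
    ("moderate_severe_liver_disease", "congestive_heart_failure", "moderate_severe_renal_disease"),
    ("aids",),
    ("metastatic_solid_tumor", "chronic_pulmonary_disease"),
)

_MAX_RETRIES = 50


class CohortConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    counts: dict[Category, int] = Field(default_factory=lambda: dict(DEFAULT_COUNTS))
    seed: int = 0

    @property
    def n_cases(self) -> int:
        return sum(self.counts.values())


def _round_psa(x: float) -> float:
    return float(round(x, 1))


def _case(record: dict) -> CaseScenario:
    return parse_case(record)


def _build_cat1(rng: np.random.Generator, case_id: str) -> CaseScenario:
    age = int(rng.integers(50, 70))
    record: dict = {"case_id": case_id, "age": age,
                    "category": Category.cat1_screen_recommended.value}
    if rng.random() < 0.3:
        record["comorbidities"] = [str(rng.choice(_LIGHT_COMORBIDITIES))]
    if rng.random() < 0.25:
        record["risk_factors"] = [str(rng.choice([rf.value for rf in RiskFactor]))]
    if rng.random() < 0.3:
        record["preference"] = Preference.requests_screening.value
    if rng.random() < 0.3:
        record["dre"] = DREStatus.normal.value
    return _case(record)


def _build_cat2(rng: np.random.Generator, case_id: str, idx: int) -> CaseScenario:
    record: dict = {"case_id": case_id, "category": Category.cat2_screen_not_recommended.value}
    if idx % 2 == 0:  # age-gate failure
        record["age"] = int(rng.integers(73, 86))
        if rng.random() < 0.5:
            record["comorbidities"] = [str(rng.choice(_LIGHT_COMORBIDITIES))]
    else:  # life-expectancy failure under heavy burden
        record["age"] = int(rng.integers(55, 73))
        record["comorbidities"] = list(
            _HEAVY_COMORBIDITIES[int(rng.integers(0, len(_HEAVY_COMORBIDITIES)))]
        )
    return _case(record)


def _build_cat3(rng: np.random.Generator, case_id: str) -> CaseScenario:
    age = int(rng.integers(50, 70))
    latest = _round_psa(float(rng.uniform(0.4, 2.8)))
    history = [{"value": latest, "months_ago": int(rng.integers(0, 4))}]
    if rng.random() < 0.6:
        history.append(
            {"value": _round_psa(float(rng.uniform(0.4, 2.8))),
             "months_ago": int(rng.integers(24, 49))}
        )
    return _case({"case_id": case_id, "age": age, "psa_history": history,
                  "category": Category.cat3_normal_followup.value})


def _build_cat4(rng: np.random.Generator, case_id: str, idx: int) -> CaseScenario:
    age = int(rng.integers(55, 70))
    if idx < 4:  # unconfirmed moderate elevation
        history = [{"value": _round_psa(float(rng.uniform(3.2, 9.5))), "months_ago": 0}]
    elif idx < 6:  # confirmed elevation
        history = [
            {"value": _round_psa(float(rng.uniform(3.5, 9.0))), "months_ago": int(rng.integers(1, 3))},
            {"value": _round_psa(float(rng.uniform(3.5, 9.5))), "months_ago": 0},
        ]
    else:  # marked elevation
        history = [{"value": _round_psa(float(rng.uniform(11.0, 35.0))), "months_ago": 0}]
    return _case({"case_id": case_id, "age": age, "psa_history": history,
                  "category": Category.cat4_elevated_psa.value})


def _build_cat5(rng: np.random.Generator, case_id: str, idx: int) -> CaseScenario:
    record: dict = {"case_id": case_id, "category": Category.cat5_other.value}
    if idx < 3:  # spurious elevation during an active UTI
        record.update(
            age=int(rng.integers(52, 70)),
            active_uti=True,
            luts=True,
            psa_history=[{"value": _round_psa(float(rng.uniform(4.0, 9.5))), "months_ago": 0}],
        )
    elif idx < 5:  # elevated PSA, prohibitive comorbidity: gate-ineligible
        record.update(
            age=int(rng.integers(74, 86)),
            comorbidities=list(_HEAVY_COMORBIDITIES[int(rng.integers(0, len(_HEAVY_COMORBIDITIES)))]),
            psa_history=[{"value": _round_psa(float(rng.uniform(4.5, 14.0))), "months_ago": 0}],
        )
    else:  # abnormal DRE with a normal PSA
        record.update(
            age=int(rng.integers(52, 70)),
            dre=DREStatus.abnormal.value,
            psa_history=[{"value": _round_psa(float(rng.uniform(0.6, 2.5))), "months_ago": 0}],
        )
    return _case(record)


_SCREENING_ACTIONS = frozenset({Action.offer_psa_now, Action.routine_interval})


def _satisfies(case: CaseScenario, gold: GoldLabel, eligible: bool) -> bool:
    actions = {a.action for a in gold.acceptable}
    cat = case.category
    if cat is Category.cat1_screen_recommended:
        return eligible and actions <= _SCREENING_ACTIONS
    if cat is Category.cat2_screen_not_recommended:
        return not eligible and actions == {Action.no_testing}
    if cat is Category.cat3_normal_followup:
        return eligible and actions == {Action.routine_interval}
    if cat is Category.cat4_elevated_psa:
        return eligible and actions <= {Action.confirmatory_repeat_weeks, Action.refer_urology}
    if cat is Category.cat5_other:
        return actions <= {
            Action.defer_treat_uti_then_repeat, Action.no_testing, Action.refer_urology
        }
    return False


def generate_cohort(
    config: Optional[CohortConfig] = None,
    rules: Optional[RuleConfig] = None,
    gate_config: Optional[GateConfig] = None,
    cci_config: Optional[CCIConfig] = None,
) -> list[tuple[CaseScenario, GoldLabel]]:
    """Generate a gold-labelled cohort under *config* (seeded, reproducible).

    Each case is re-sampled (bounded retries) until it satisfies its
    category's defining constraints under the supplied gate and rule
    configuration; an unsatisfiable configuration — e.g. category-2 cases
    requested with the gate disabled — raises :class:`GenerationError`.
    """
    config = config or CohortConfig()
    rules = rules or default_rules()
    builders = {
        Category.cat1_screen_recommended: lambda rng, cid, i: _build_cat1(rng, cid),
        Category.cat2_screen_not_recommended: _build_cat2,
        Category.cat3_normal_followup: lambda rng, cid, i: _build_cat3(rng, cid),
        Category.cat4_elevated_psa: _build_cat4,
        Category.cat5_other: _build_cat5,
    }
    seeds = np.random.SeedSequence(config.seed).spawn(len(Category))
    cohort: list[tuple[CaseScenario, GoldLabel]] = []
    for category, child in zip(Category, seeds):
        n = config.counts.get(category, 0)
        if n < 0:
            raise ValueError(f"negative count for {category.value}")
        rng = np.random.default_rng(child)
        build = builders[category]
        for i in range(n):
            case_id = f"syn-{category.value.split('_')[0]}-{i:02d}"
            for _attempt in range(_MAX_RETRIES):
                case = build(rng, case_id, i)
                gate = screening_gate(case, cci_score(case, cci_config), gate_config)
                gold = gold_from_engine(case, gate, rules)
                if _satisfies(case, gold, gate.eligible):
                    cohort.append((case, gold))
                    break
            else:
                raise GenerationError(
                    f"could not satisfy constraints for {category.value} case {i} "
                    f"after {_MAX_RETRIES} attempts (check gate/rule configuration)"
                )
    return cohort


def degrade_ratings(
    cohort: Sequence[tuple[CaseScenario, GoldLabel]],
    error_profile: dict[Category, dict[ErrorType, float]],
    seed: int = 0,
    arm: Arm = Arm.human_closed,
    n_raters: int = 5,
) -> list[GradedRating]:
    """Simulate an imperfect rater arm over an engine-consistent cohort.

    For each (case, rater) cell an error subtype is drawn with the
    category's configured probability (remaining mass is a correct
    rating), so expected subtype frequencies equal the profile. Rates must
    lie in [0, 1] and sum to at most 1 per category.
    """
    for cat, rates in error_profile.items():
        for et, rate in rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate for {cat.value}/{et.value} outside [0,1]: {rate}")
        if sum(rates.values()) > 1.0 + 1e-9:
            raise ValueError(f"error rates for {cat.value} sum to more than 1")
    rng = np.random.default_rng(seed)
    ratings: list[GradedRating] = []
    for case, gold in cohort:
        rates = error_profile.get(gold.category, {})
        subtypes = list(rates)
        cum = np.cumsum([rates[s] for s in subtypes]) if subtypes else np.array([])
        for j in range(n_raters):
            u = rng.random()
            error = ErrorType.none
            for k, edge in enumerate(cum):
                if u < edge:
                    error = subtypes[k]
                    break
            ratings.append(
                GradedRating(
                    case_id=gold.case_id,
                    arm=arm,
                    rater_id=f"r{j + 1}",
                    correct=error is ErrorType.none,
                    error=error,
                    category=gold.category,
                )
            )
    return ratings
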
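"""Case-scenario data model.

A :class:`CaseScenario` is one outpatient vignette: demographics, coded
comorbidities (controlled vocabulary = the 19 Charlson items), urological
symptoms, digital rectal examination (DRE) status, a chronological PSA
history, risk factors and patient preference. Every downstream stage —
the Charlson gate, the guideline engine, the RAG pipeline, the evaluation
harness — consumes these records.

Time is encoded as ``months_ago`` relative to the consult; vignettes are
relative, not dated. Free text is carried but never parsed by the
deterministic core.
"""
from __future__ import annotations

import json
from enum import Enum
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import CaseSchemaError, VocabularyError

#: Controlled comorbidity vocabulary: the 19 Charlson conditions plus "none".
#: Unknown strings are errors, not silently ignored — a silently dropped code
#: would corrupt the comorbidity score downstream.
CHARLSON_CONDITIONS = (
    "myocardial_infarction",
    "congestive_heart_failure",
    "peripheral_vascular_disease",
    "cerebrovascular_disease",
    "dementia",
    "chronic_pulmonary_disease",
    "connective_tissue_disease",
    "peptic_ulcer_disease",
    "mild_liver_disease",
    "diabetes_uncomplicated",
    "hemiplegia",
    "moderate_severe_renal_disease",
    "diabetes_with_end_organ_damage",
    "solid_tumor",
    "leukemia",
    "lymphoma",
    "moderate_severe_liver_disease",
    "metastatic_solid_tumor",
    "aids",
)

COMORBIDITY_VOCABULARY = frozenset(CHARLSON_CONDITIONS) | {"none"}


class PSAContext(str, Enum):
    screening = "screening"
    follow_up = "follow_up"
    symptomatic = "symptomatic"


class DREStatus(str, Enum):
    not_done = "not_done"
    normal = "normal"
    abnormal = "abnormal"


class RiskFactor(str, Enum):
    family_history_prostate_ca = "family_history_prostate_ca"
    brca_carrier = "brca_carrier"
    african_ancestry = "african_ancestry"


class Preference(str, Enum):
    requests_screening = "requests_screening"
    declines = "declines"
    unstated = "unstated"


class Category(str, Enum):
    """The five study case categories."""

    cat1_screen_recommended = "cat1_screen_recommended"
    cat2_screen_not_recommended = "cat2_screen_not_recommended"
    cat3_normal_followup = "cat3_normal_followup"
    cat4_elevated_psa = "cat4_elevated_psa"
    cat5_other = "cat5_other"


class PSAReading(BaseModel):
    """One serum PSA measurement in ng/mL, ``months_ago`` before the consult."""

    model_config = ConfigDict(frozen=True)

    value: float = Field(ge=0, description="PSA concentration in ng/mL")
    months_ago: int = Field(ge=0)
    context: Optional[PSAContext] = None


class CaseScenario(BaseModel):
    model_config = ConfigDict(frozen=True)

    case_id: str
    age: int = Field(ge=18, le=120, description="age in years")
    comorbidities: tuple[str, ...] = ()
    luts: bool = False
    hematuria: bool = False
    active_uti: bool = False
    dre: DREStatus = DREStatus.not_done
    psa_history: tuple[PSAReading, ...] = ()
    risk_factors: tuple[RiskFactor, ...] = ()
    preference: Preference = Preference.unstated
    free_text: Optional[str] = None
    category: Optional[Category] = None

    @field_validator("comorbidities")
    @classmethod
    def _check_vocabulary(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        unknown = {c for c in v if c not in COMORBIDITY_VOCABULARY}
        if unknown:
            raise VocabularyError(unknown, COMORBIDITY_VOCABULARY)
        # "none" is an explicit marker for an empty burden; normalise it away
        return tuple(c for c in v if c != "none")

    @field_validator("psa_history")
    @classmethod
    def _sort_history(cls, v: tuple[PSAReading, ...]) -> tuple[PSAReading, ...]:
        offsets = [r.months_ago for r in v]
        if len(set(offsets)) != len(offsets):
            raise ValueError("at most one PSA reading per months_ago value")
        # oldest first: months_ago descending
        return tuple(sorted(v, key=lambda r: -r.months_ago))


def parse_case(record: Mapping[str, Any]) -> CaseScenario:
    """Validate a structured case record into a :class:`CaseScenario`.

    Optional fields default to absent/false/unstated; the PSA history is
    re-sorted chronologically (oldest first). Raises
    :class:`~psaguide.errors.CaseSchemaError` naming the offending field on a
    schema violation and :class:`~psaguide.errors.VocabularyError` (listing
    the accepted codes) on an unknown comorbidity code.
    """
    if not isinstance(record, Mapping):
        raise CaseSchemaError("case record must be a mapping")
    try:
        return CaseScenario.model_validate(dict(record))
    except ValidationError as exc:
        for err in exc.errors():
            ctx_err = err.get("ctx", {}).get("error")
            if isinstance(ctx_err, VocabularyError):
                raise ctx_err from exc
        fields = ", ".join(
            ".".join(str(p) for p in err["loc"]) or "<record>" for err in exc.errors()
        )
        raise CaseSchemaError(f"invalid case record (field(s): {fields}): {exc}") from exc


def latest_psa(case: CaseScenario) -> Optional[PSAReading]:
    """The most recent PSA reading (smallest ``months_ago``), or ``None``."""
    if not case.psa_history:
        return None
    return min(case.psa_history, key=lambda r: r.months_ago)


def serialize_case(case: CaseScenario) -> dict[str, Any]:
    """Canonical JSON-compatible dict (enums as strings, None fields kept)."""
    return case.model_dump(mode="json")


def case_to_json(case: CaseScenario) -> str:
    """Canonical JSON with sorted keys — hash-stable across runs."""
    return json.dumps(serialize_case(case), sort_keys=True)


def read_case(path: str | Path) -> CaseScenario:
    """Read one case record from a ``.json`` or ``.yaml``/``.yml`` file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        record = yaml.safe_load(text)
    else:
        record = json.loads(text)
    return parse_case(record)


def write_case(case: CaseScenario, path: str | Path) -> None:
    Path(path).write_text(case_to_json(case) + "\n")


def case_schema() -> dict[str, Any]:
    """JSON Schema for on-disk case records (also shipped in package data)."""
    return CaseScenario.model_json_schema()
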
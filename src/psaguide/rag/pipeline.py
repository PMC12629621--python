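"""End-to-end pipeline orchestration.

Stages run in a fixed order: Charlson scoring → gates → (if eligible)
per-guideline retrieval → prompt assembly → generation → reconciliation.
Gate-ineligible cases short-circuit with a refusal carrying the gate
reasons and never touch the retriever or a backend. Every executed stage
appends to an ordered trace, which is what the constrain-to-context audit
and the short-circuit tests inspect.
"""
from __future__ import annotations

import json
from typing import Optional

from pydantic import BaseModel, ConfigDict

from ..cases import CaseScenario, latest_psa
from ..cci import CCIResult, GateConfig, GateDecision, cci_score, screening_gate
from ..engine import DualRecommendation, RuleConfig, Source, default_rules, reconcile
from ..errors import PipelineStageError, PsaGuideError
from .backends import GenerationBackend, generate
from .corpus import ChunkConfig, chunk_corpus, default_corpus_dir, load_corpus
from .prompts import assemble_prompt
from .retrieval import BM25Index, RetrievalResult


class TraceEntry(BaseModel):
    model_config = ConfigDict(frozen=True)

    stage: str
    detail: str


class PipelineResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    case_id: str
    cci: CCIResult
    gate: GateDecision
    retrieval: dict[str, tuple[RetrievalResult, ...]] = {}
    dual: Optional[DualRecommendation] = None
    trace: tuple[TraceEntry, ...] = ()

    def to_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True)


class PipelineConfig:
    """Everything one run needs: backend, index, rules, gate, retrieval knobs."""

    def __init__(
        self,
        backend: GenerationBackend,
        index: Optional[BM25Index] = None,
        rules: Optional[RuleConfig] = None,
        gate_config: Optional[GateConfig] = None,
        k: int = 6,
        min_score: float = 0.0,
        template: Optional[str] = None,
    ):
        self.backend = backend
        self.index = index if index is not None else default_index()
        self.rules = rules or default_rules()
        self.gate_config = gate_config
        self.k = k
        self.min_score = min_score
        self.template = template


def default_index(chunk_config: Optional[ChunkConfig] = None) -> BM25Index:
    """Index over the packaged fixture corpus."""
    return BM25Index(chunk_corpus(load_corpus(default_corpus_dir()), chunk_config))


def build_query(case: CaseScenario) -> str:
    """Deterministic retrieval query summarising the decision-relevant facts."""
    parts = [
        "prostate specific antigen PSA testing screening recommendation",
        f"age {case.age} years screening interval follow-up",
    ]
    latest = latest_psa(case)
    if latest is None:
        parts.append("baseline PSA offer early detection")
    else:
        parts.append(f"PSA {latest.value} ng/mL threshold elevated repeat confirm")
    if case.active_uti:
        parts.append("urinary tract infection spurious elevation")
    if case.dre.value == "abnormal":
        parts.append("abnormal digital rectal examination referral")
    if case.risk_factors:
        parts.append("family history risk adapted early")
    if case.luts or case.hematuria:
        parts.append("lower urinary tract symptoms")
    return " ".join(parts)


def _run_stage(trace: list[TraceEntry], stage: str, fn):
    try:
        result = fn()
    except PsaGuideError as exc:
        raise PipelineStageError(stage, exc) from exc
    except Exception as exc:  # annotate unexpected errors with the stage name
        raise PipelineStageError(stage, exc) from exc
    return result


def run_pipeline(case: CaseScenario, config: PipelineConfig) -> PipelineResult:
    """Run one case through the full workflow.

    Gate-ineligible cases return a refusal (``dual is None``) whose gate
    decision carries the reasons; no retrieval is performed and no backend
    is called for them.
    """
    trace: list[TraceEntry] = []

    cci = _run_stage(trace, "cci", lambda: cci_score(case))
    trace.append(TraceEntry(stage="cci", detail=f"score={cci.score} survival={cci.ten_year_survival:.3f}"))

    gate = _run_stage(trace, "gate", lambda: screening_gate(case, cci, config.gate_config))
    trace.append(TraceEntry(
        stage="gate",
        detail="eligible" if gate.eligible else "refused:" + ",".join(r.value for r in gate.reasons),
    ))
    if not gate.eligible:
        trace.append(TraceEntry(stage="refusal", detail="short-circuit; no retrieval or generation"))
        return PipelineResult(case_id=case.case_id, cci=cci, gate=gate, trace=tuple(trace))

    query = build_query(case)
    retrieval: dict[str, tuple[RetrievalResult, ...]] = {}
    recs = {}
    for source in (Source.EAU, Source.AUA):
        results = _run_stage(
            trace, f"retrieve:{source.value}",
            lambda s=source: config.index.retrieve(query, s, k=config.k, min_score=config.min_score),
        )
        retrieval[source.value] = tuple(results)
        trace.append(TraceEntry(
            stage=f"retrieve:{source.value}",
            detail=";".join(f"{r.rank}:{r.chunk.chunk_id}:{r.score:.3f}" for r in results),
        ))

        bundle = _run_stage(
            trace, f"prompt:{source.value}",
            lambda r=results: assemble_prompt(case, r, config.template),
        )
        trace.append(TraceEntry(stage=f"prompt:{source.value}", detail=f"{len(bundle.context_blocks)} context blocks"))

        rec = _run_stage(
            trace, f"generate:{source.value}",
            lambda b=bundle: generate(case, b, config.backend, config.template),
        )
        recs[source] = rec
        trace.append(TraceEntry(stage=f"generate:{source.value}", detail=f"action={rec.action.value}"))

        supported = {rid for r in results for rid in r.chunk.rule_ids}
        unsupported = [
            rid for rid in rec.rationale
            if rid not in supported and not rid.startswith("gate.")
        ]
        trace.append(TraceEntry(
            stage=f"context_check:{source.value}",
            detail="ok" if not unsupported else "unsupported:" + ",".join(unsupported),
        ))

    dual = _run_stage(trace, "reconcile", lambda: reconcile(recs[Source.EAU], recs[Source.AUA]))
    trace.append(TraceEntry(
        stage="reconcile",
        detail=("concordant:" if dual.concordant else "discordant:")
        + ",".join(f.action.value for f in dual.final_actions),
    ))
    return PipelineResult(
        case_id=case.case_id, cci=cci, gate=gate,
        retrieval=retrieval, dual=dual, trace=tuple(trace),
    )


def uncited_context_rules(result: PipelineResult) -> list[str]:
    """Rule ids cited by the recommendations without a retrieved supporting
    passage — non-empty means the constrain-to-context audit failed."""
    out: list[str] = []
    for entry in result.trace:
        if entry.stage.startswith("context_check:") and entry.detail != "ok":
            out.extend(entry.detail.removeprefix("unsupported:").split(","))
    return out
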
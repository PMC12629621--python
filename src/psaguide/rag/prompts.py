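"""Prompt assembly for the generation backends.

A :class:`PromptBundle` packages the four prompting techniques the
pipeline relies on: an expert-clinician persona, chain-of-thought
reasoning instructions, a constrain-to-retrieved-context directive, and an
example output structure that parses under the strict response parser.
Every retrieved passage appears verbatim (with source attribution) in the
bundle, and rendering is byte-deterministic, so a backend sees exactly the
evidence the retriever produced.
"""
from __future__ import annotations

import json
import re
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict

from ..cases import CaseScenario, case_to_json
from ..engine import Source
from ..errors import TemplateError
from .retrieval import RetrievalResult

REQUIRED_SLOTS = ("persona", "source", "case_json", "context", "reasoning", "output_schema")

PERSONA_PREAMBLE = (
    "You are an experienced consultant urologist advising on prostate-specific "
    "antigen (PSA) testing in an outpatient clinic. You answer strictly "
    "according to the guideline excerpts you are given."
)

REASONING_INSTRUCTION = (
    "Think step by step: identify the patient's age band, PSA status and any "
    "special findings, then locate the applicable guideline statements in the "
    "context above. Base the recommendation ONLY on the guideline context "
    "provided; if the context does not support a recommendation, say so. Cite "
    "the bracketed rule identifiers of every statement you rely on."
)

#: Example output structure; must parse under backends.parse_response.
OUTPUT_SCHEMA_EXAMPLE = json.dumps(
    {
        "action": "routine_interval",
        "interval_months": [24, 48],
        "shared_decision": True,
        "rules": ["aua.routine_screening_band"],
        "reasoning": "Average-risk man aged 50-69 on a screening programme.",
    },
    indent=2,
)


class PromptBundle(BaseModel):
    model_config = ConfigDict(frozen=True)

    source: Source
    persona_preamble: str
    case_text: str
    context_blocks: tuple[str, ...]
    reasoning_instruction: str
    output_schema_example: str


def default_template() -> str:
    return resources.files("psaguide").joinpath("data", "prompt_template.txt").read_text()


def load_template(path: str | Path) -> str:
    return Path(path).read_text()


def _check_template(template: str) -> None:
    slots = set(re.findall(r"\{([a-z_]+)\}", template))
    missing = [s for s in REQUIRED_SLOTS if s not in slots]
    if missing:
        raise TemplateError(f"prompt template missing required slot(s): {missing}")


def assemble_prompt(
    case: CaseScenario,
    results: Sequence[RetrievalResult],
    template: Optional[str] = None,
) -> PromptBundle:
    """Build the prompt bundle for one guideline's retrieved context.

    Pre: *results* is non-empty and single-source (per-guideline retrieval
    guarantees this). The retrieved passages are embedded verbatim, each
    with source/section attribution and its rule identifiers.
    """
    if not results:
        raise ValueError("assemble_prompt requires at least one retrieval result")
    sources = {r.chunk.source for r in results}
    if len(sources) != 1:
        raise ValueError(f"retrieved context mixes guideline sources: {sources}")
    _check_template(template if template is not None else default_template())
    (source,) = sources
    blocks = tuple(
        f"[{r.chunk.source.value} | {r.chunk.section} | rules: "
        f"{', '.join(r.chunk.rule_ids) or '-'}]\n{r.chunk.text}"
        for r in results
    )
    return PromptBundle(
        source=source,
        persona_preamble=PERSONA_PREAMBLE,
        case_text=case_to_json(case),
        context_blocks=blocks,
        reasoning_instruction=REASONING_INSTRUCTION,
        output_schema_example=OUTPUT_SCHEMA_EXAMPLE,
    )


def render_prompt(bundle: PromptBundle, template: Optional[str] = None) -> str:
    """Deterministic text rendering of a bundle (same inputs → same bytes)."""
    template = template if template is not None else default_template()
    _check_template(template)
    return template.format(
        persona=bundle.persona_preamble,
        source=bundle.source.value,
        case_json=bundle.case_text,
        context="\n\n".join(bundle.context_blocks),
        reasoning=bundle.reasoning_instruction,
        output_schema=bundle.output_schema_example,
    )
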
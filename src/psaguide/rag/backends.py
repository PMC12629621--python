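"""Generation backends and the strict response parser.

The backend contract is minimal — a callable from prompt text to response
text — so commercial APIs, local models, the deterministic mock and
scripted replays are interchangeable. No networked backend is required
anywhere in the package:

* :class:`MockGuidelineBackend` answers by re-reading the case out of the
  prompt and delegating to the deterministic rule engine, making the whole
  pipeline exercisable offline (and its accuracy on engine-labelled gold
  exactly 100%, so any deviation is attributable).
* :class:`ScriptedBackend` replays canned responses keyed by
  ``(case_id, source)`` — the vehicle for failure-mode tests such as the
  hallucinated confirmatory repeat on a PSA of 2.8 ng/mL.

Responses must be a single strict JSON object (action, optional interval,
cited rules, reasoning); strictness is what makes hallucination
detectable. Parse failures and backend failures are distinct error types.
"""
from __future__ import annotations

import json
import re
from typing import Callable, Mapping, Optional

from ..cases import CaseScenario, parse_case
from ..cci import GateConfig, cci_score, screening_gate
from ..engine import (
    Action,
    Recommendation,
    RuleConfig,
    Source,
    default_rules,
    recommend_aua,
    recommend_eau,
)
from ..errors import BackendError, ResponseParseError
from .prompts import PromptBundle, render_prompt

#: Backend contract: prompt text in, structured response text out.
GenerationBackend = Callable[[str], str]

_SOURCE_MARK = re.compile(r"^### SOURCE: (\w+)\s*$", re.MULTILINE)
_CASE_MARK = re.compile(r"^### CASE\n(.*?)\n### ", re.MULTILINE | re.DOTALL)


def _extract_source(prompt: str) -> Source:
    m = _SOURCE_MARK.search(prompt)
    if not m:
        raise BackendError("prompt carries no '### SOURCE:' marker")
    return Source(m.group(1))


def _extract_case(prompt: str) -> CaseScenario:
    m = _CASE_MARK.search(prompt)
    if not m:
        raise BackendError("prompt carries no '### CASE' block")
    return parse_case(json.loads(m.group(1).strip()))


def recommendation_to_response(rec: Recommendation, reasoning: str = "") -> str:
    """Serialize a Recommendation as a backend response string."""
    return json.dumps(
        {
            "action": rec.action.value,
            "interval_months": list(rec.interval_months) if rec.interval_months else None,
            "shared_decision": rec.shared_decision,
            "rules": list(rec.rationale),
            "reasoning": reasoning,
        },
        sort_keys=True,
    )


class MockGuidelineBackend:
    """Deterministic backend delegating to the rule engine."""

    def __init__(
        self,
        rules: Optional[RuleConfig] = None,
        gate_config: Optional[GateConfig] = None,
    ):
        self.rules = rules or default_rules()
        self.gate_config = gate_config

    def __call__(self, prompt: str) -> str:
        source = _extract_source(prompt)
        case = _extract_case(prompt)
        gate = screening_gate(case, cci_score(case), self.gate_config)
        rec = (recommend_eau if source is Source.EAU else recommend_aua)(
            case, gate, self.rules
        )
        return recommendation_to_response(
            rec, reasoning=f"rule-engine answer for {case.case_id} under {source.value}"
        )


class ScriptedBackend:
    """Replays canned responses keyed by ``(case_id, source)``.

    Keys may be 2-tuples or ``"case_id|SOURCE"`` strings (the on-disk
    form). A missing script entry is a backend error.
    """

    def __init__(self, responses: Mapping):
        self.responses: dict[tuple[str, str], str] = {}
        for key, value in responses.items():
            if isinstance(key, str):
                cid, src = key.split("|", 1)
            else:
                cid, src = key
            self.responses[(cid, str(src))] = value
        self.calls: list[tuple[str, str]] = []

    def __call__(self, prompt: str) -> str:
        source = _extract_source(prompt)
        case = _extract_case(prompt)
        key = (case.case_id, source.value)
        self.calls.append(key)
        try:
            return self.responses[key]
        except KeyError:
            raise BackendError(f"no scripted response for {key}") from None


def parse_response(text: str, source: Source) -> Recommendation:
    """Parse a backend response into a :class:`Recommendation`, strictly.

    The response must be exactly one JSON object with a valid ``action``;
    anything else raises :class:`ResponseParseError` carrying the raw text.
    """
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ResponseParseError(f"response is not valid JSON ({exc.msg})", raw=text) from exc
    if not isinstance(payload, dict):
        raise ResponseParseError("response JSON is not an object", raw=text)
    try:
        action = Action(payload["action"])
    except KeyError:
        raise ResponseParseError("response lacks an 'action' field", raw=text) from None
    except ValueError:
        raise ResponseParseError(
            f"unknown action {payload.get('action')!r}", raw=text
        ) from None
    interval = payload.get("interval_months")
    try:
        return Recommendation(
            source=source,
            action=action,
            interval_months=tuple(interval) if interval is not None else None,
            shared_decision=bool(payload.get("shared_decision", False)),
            rationale=tuple(payload.get("rules", ())),
        )
    except ValueError as exc:
        raise ResponseParseError(f"inconsistent response fields: {exc}", raw=text) from exc


def generate(
    case: CaseScenario,
    bundle: PromptBundle,
    backend: GenerationBackend,
    template: Optional[str] = None,
) -> Recommendation:
    """Render the bundle, call the backend, parse the structured response.

    Backend failures surface as :class:`BackendError`; malformed responses
    as :class:`ResponseParseError` — the two are deliberately distinct.
    """
    prompt = render_prompt(bundle, template)
    try:
        raw = backend(prompt)
    except (BackendError, ResponseParseError):
        raise
    except Exception as exc:
        raise BackendError(f"generation backend failed: {exc}") from exc
    return parse_response(raw, bundle.source)
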
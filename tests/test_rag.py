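"""Retrieval-augmented pipeline: chunking, BM25, prompts, backends, orchestration."""
import json
import math

import pytest

from psaguide import Action, Source, parse_case, recommend_eau, cci_score, screening_gate
from psaguide.errors import (
    BackendError,
    ConfigurationError,
    ResponseParseError,
    TemplateError,
)
from psaguide.rag import (
    BM25Index,
    ChunkConfig,
    CorpusDocument,
    MockGuidelineBackend,
    PipelineConfig,
    ScriptedBackend,
    assemble_prompt,
    chunk_corpus,
    generate,
    load_chunks,
    parse_response,
    render_prompt,
    run_pipeline,
    save_chunks,
    uncited_context_rules,
)
from psaguide.rag.corpus import load_corpus
from psaguide.rag.prompts import OUTPUT_SCHEMA_EXAMPLE
from psaguide.rag.retrieval import BM25_B, BM25_K1, tokenize


def _doc(text, source=Source.EAU, section="s"):
    return CorpusDocument(source=source, section=section, text=text)


class TestChunking:
    def test_small_document_is_one_chunk(self):
        doc = _doc("para one.\n\npara two.\n\npara three.")
        chunks = chunk_corpus([doc], ChunkConfig(max_tokens=1000, overlap=0))
        assert len(chunks) == 1
        assert "para one." in chunks[0].text and "para three." in chunks[0].text

    def test_chunk_ids_stable_across_runs(self):
        docs = [_doc("alpha beta.\n\ngamma delta.", section="x")]
        ids1 = [c.chunk_id for c in chunk_corpus(docs)]
        ids2 = [c.chunk_id for c in chunk_corpus(docs)]
        assert ids1 == ids2

    def test_empty_document_yields_no_chunks(self, caplog):
        with caplog.at_level("WARNING"):
            assert chunk_corpus([_doc("   ")]) == []
        assert any("empty" in r.message for r in caplog.records)

    def test_splits_respect_token_budget(self):
        paragraphs = [f"word{i} " * 40 for i in range(6)]
        doc = _doc("\n\n".join(paragraphs))
        chunks = chunk_corpus([doc], ChunkConfig(max_tokens=100, overlap=0))
        assert len(chunks) > 1
        assert all(c.token_estimate <= 100 for c in chunks)

    def test_rule_tags_extracted_and_stripped(self):
        doc = _doc("[eau.alpha] [eau.beta] Offer a test.\n\n[eau.gamma] Stop testing.")
        chunks = chunk_corpus([doc], ChunkConfig(max_tokens=1000))
        assert chunks[0].rule_ids == ("eau.alpha", "eau.beta", "eau.gamma")
        assert "[eau.alpha]" not in chunks[0].text

    def test_untagged_corpus_file_is_config_error(self, tmp_path):
        (tmp_path / "doc.md").write_text("no front matter here")
        with pytest.raises(ConfigurationError):
            load_corpus(tmp_path)

    def test_chunks_jsonl_round_trip(self, tmp_path):
        chunks = chunk_corpus([_doc("alpha beta.\n\ngamma delta.")])
        save_chunks(chunks, tmp_path / "chunks.jsonl")
        assert load_chunks(tmp_path / "chunks.jsonl") == chunks


TOY_TEXTS = [
    "psa testing threshold elevated",
    "screening interval two years psa",
    "digital rectal examination referral",
]


@pytest.fixture()
def toy_index():
    chunks = chunk_corpus([_doc(t) for t in TOY_TEXTS], ChunkConfig(max_tokens=100))
    return BM25Index(chunks)


def _bm25_oracle(query, texts, k1=BM25_K1, b=BM25_B):
    """Independent brute-force Okapi BM25 (idf = ln(1 + (N-df+.5)/(df+.5)))."""
    docs = [tokenize(t) for t in texts]
    n = len(docs)
    avgdl = sum(len(d) for d in docs) / n
    scores = []
    for d in docs:
        s = 0.0
        for term in tokenize(query):
            df = sum(1 for other in docs if term in other)
            f = d.count(term)
            if f == 0:
                continue
            idf = math.log(1 + (n - df + 0.5) / (df + 0.5))
            s += idf * f * (k1 + 1) / (f + k1 * (1 - b + b * len(d) / avgdl))
        scores.append(s)
    return scores


class TestRetrieval:
    def test_scores_match_brute_force_oracle(self, toy_index):
        query = "psa threshold interval"
        results = toy_index.retrieve(query, Source.EAU, k=3)
        oracle = _bm25_oracle(query, TOY_TEXTS)
        by_text = {r.chunk.text: r.score for r in results}
        for text, expected in zip(TOY_TEXTS, oracle):
            assert by_text[text] == pytest.approx(expected, rel=1e-12)

    def test_self_retrieval_rank_one(self, toy_index):
        results = toy_index.retrieve(TOY_TEXTS[2], Source.EAU, k=3)
        assert results[0].chunk.text == TOY_TEXTS[2]
        assert results[0].rank == 1

    def test_k_larger_than_corpus_gives_dense_ranks(self, toy_index):
        results = toy_index.retrieve("psa", Source.EAU, k=50)
        assert [r.rank for r in results] == list(range(1, len(results) + 1))

    def test_scores_non_increasing_with_rank(self, toy_index):
        results = toy_index.retrieve("psa testing years", Source.EAU, k=10)
        scores = [r.score for r in results]
        assert scores == sorted(scores, reverse=True)

    def test_k_below_one_is_domain_error(self, toy_index):
        with pytest.raises(ValueError):
            toy_index.retrieve("psa", Source.EAU, k=0)

    def test_missing_source_namespace_errors(self, toy_index):
        with pytest.raises(ValueError):
            toy_index.retrieve("psa", Source.AUA, k=1)

    def test_min_score_drops_low_scores(self, toy_index):
        all_results = toy_index.retrieve("psa", Source.EAU, k=10)
        filtered = toy_index.retrieve("psa", Source.EAU, k=10, min_score=1e9)
        assert len(filtered) < len(all_results)

    def test_retrieval_deterministic(self, index):
        a = index.retrieve("psa threshold elevated", Source.EAU, k=5)
        b = index.retrieve("psa threshold elevated", Source.EAU, k=5)
        assert a == b


class TestPrompts:
    def test_retrieved_passages_verbatim_in_context(self, index):
        case = parse_case({"case_id": "p1", "age": 55})
        results = index.retrieve("psa screening", Source.AUA, k=2)
        bundle = assemble_prompt(case, results)
        for r in results:
            assert any(r.chunk.text in block for block in bundle.context_blocks)
        rendered = render_prompt(bundle)
        for r in results:
            assert r.chunk.text in rendered

    def test_rendering_is_byte_deterministic(self, index):
        case = parse_case({"case_id": "p2", "age": 61})
        results = index.retrieve("psa interval", Source.EAU, k=2)
        assert render_prompt(assemble_prompt(case, results)) == render_prompt(
            assemble_prompt(case, results)
        )

    def test_template_missing_slot_is_error(self, index):
        case = parse_case({"case_id": "p3", "age": 55})
        results = index.retrieve("psa", Source.EAU, k=1)
        with pytest.raises(TemplateError):
            assemble_prompt(case, results, template="{persona} {case_json}")

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            assemble_prompt(parse_case({"case_id": "p4", "age": 55}), [])

    def test_output_schema_example_parses_under_response_parser(self):
        rec = parse_response(OUTPUT_SCHEMA_EXAMPLE, Source.AUA)
        assert rec.action is Action.routine_interval


class TestBackends:
    def _bundle(self, index, case, source=Source.EAU):
        return assemble_prompt(case, index.retrieve("psa screening", source, k=6))

    def test_mock_backend_reproduces_rule_engine(self, index):
        case = parse_case(
            {"case_id": "b1", "age": 55, "psa_history": [{"value": 2.8, "months_ago": 0}]}
        )
        rec = generate(case, self._bundle(index, case), MockGuidelineBackend())
        gate = screening_gate(case, cci_score(case))
        assert rec == recommend_eau(case, gate)

    def test_scripted_hallucination_replay(self, index):
        case = parse_case(
            {"case_id": "b2", "age": 55, "psa_history": [{"value": 2.8, "months_ago": 0}]}
        )
        hallucination = json.dumps(
            {
                "action": "confirmatory_repeat_weeks",
                "interval_months": None,
                "rules": ["eau.psa_confirmatory_repeat"],
                "reasoning": "PSA considered moderately elevated; repeat in a few weeks.",
            }
        )
        backend = ScriptedBackend({("b2", "EAU"): hallucination})
        rec = generate(case, self._bundle(index, case), backend)
        assert rec.action is Action.confirmatory_repeat_weeks

    def test_unparseable_response_is_parse_error_with_raw(self, index):
        case = parse_case({"case_id": "b3", "age": 55})
        backend = ScriptedBackend({("b3", "EAU"): "I would simply repeat the PSA."})
        with pytest.raises(ResponseParseError) as exc:
            generate(case, self._bundle(index, case), backend)
        assert "repeat the PSA" in exc.value.raw

    def test_backend_failure_is_distinct_from_parse_error(self, index):
        case = parse_case({"case_id": "b4", "age": 55})

        def broken(prompt: str) -> str:
            raise TimeoutError("backend timed out")

        with pytest.raises(BackendError):
            generate(case, self._bundle(index, case), broken)
        # missing scripted entry is also a backend error
        with pytest.raises(BackendError):
            generate(case, self._bundle(index, case), ScriptedBackend({}))

    def test_unknown_action_rejected(self):
        with pytest.raises(ResponseParseError):
            parse_response(json.dumps({"action": "order_mri"}), Source.EAU)


class TestPipeline:
    def test_gate_refusal_short_circuits(self, index):
        calls = []

        def counting_backend(prompt: str) -> str:
            calls.append(prompt)
            return "{}"

        case = parse_case({"case_id": "g1", "age": 75})
        result = run_pipeline(case, PipelineConfig(backend=counting_backend, index=index))
        assert result.dual is None
        assert not result.gate.eligible
        assert calls == []
        stages = [t.stage for t in result.trace]
        assert "refusal" in stages
        assert not any(s.startswith("retrieve") for s in stages)

    def test_eligible_case_matches_engine_end_to_end(self, mock_pipeline):
        case = parse_case(
            {"case_id": "g2", "age": 60, "psa_history": [{"value": 1.5, "months_ago": 0}]}
        )
        result = run_pipeline(case, mock_pipeline)
        gate = screening_gate(case, cci_score(case))
        assert result.dual is not None
        assert result.dual.eau == recommend_eau(case, gate)

    def test_five_runs_identical(self, mock_pipeline):
        case = parse_case({"case_id": "g3", "age": 57})
        payloads = {run_pipeline(case, mock_pipeline).to_json() for _ in range(5)}
        assert len(payloads) == 1

    def test_constrain_to_context_audit_clean_on_cohort(self, cohort, mock_pipeline):
        for case, _ in cohort:
            result = run_pipeline(case, mock_pipeline)
            assert uncited_context_rules(result) == []

    def test_trace_covers_every_executed_stage(self, mock_pipeline):
        case = parse_case({"case_id": "g4", "age": 57})
        stages = [t.stage for t in run_pipeline(case, mock_pipeline).trace]
        for expected in (
            "cci", "gate", "retrieve:EAU", "prompt:EAU", "generate:EAU",
            "context_check:EAU", "retrieve:AUA", "generate:AUA", "reconcile",
        ):
            assert expected in stages
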
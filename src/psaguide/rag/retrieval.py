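"""Lexical retrieval over the guideline corpus.

Okapi BM25 (k1 = 1.2, b = 0.75) is the default relevance scorer, with the
non-negative idf variant ``ln(1 + (N - df + 0.5)/(df + 0.5))``. Retrieval
is per-guideline: document frequencies and average length are computed
within each source namespace, so a single index with a source filter
behaves identically to two physical indexes — one per guideline — which is
what the per-guideline answer generation requires. Scoring, top-k cutoff
and the chunk-id tie-break are fully deterministic.
"""
from __future__ import annotations

import math
import re
from collections import Counter
from typing import Iterable, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from ..engine import Source
from .corpus import GuidelineChunk

_WORD = re.compile(r"[a-z0-9.]+")

BM25_K1 = 1.2
BM25_B = 0.75


def tokenize(text: str) -> list[str]:
    return _WORD.findall(text.lower())


class RetrievalResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    chunk: GuidelineChunk
    score: float
    rank: int = Field(ge=1)

    @model_validator(mode="after")
    def _finite(self) -> "RetrievalResult":
        if not math.isfinite(self.score):
            raise ValueError("retrieval score must be finite")
        return self


class _Namespace:
    """BM25 statistics for the chunks of one guideline source."""

    def __init__(self, chunks: list[GuidelineChunk], k1: float, b: float):
        self.chunks = chunks
        self.k1, self.b = k1, b
        self.doc_tokens = [Counter(tokenize(c.text)) for c in chunks]
        self.doc_len = [sum(t.values()) for t in self.doc_tokens]
        self.avgdl = sum(self.doc_len) / len(self.doc_len)
        self.df: Counter[str] = Counter()
        for toks in self.doc_tokens:
            self.df.update(toks.keys())
        self.n = len(chunks)

    def idf(self, term: str) -> float:
        df = self.df.get(term, 0)
        return math.log(1.0 + (self.n - df + 0.5) / (df + 0.5))

    def score(self, query_terms: list[str], i: int) -> float:
        tf = self.doc_tokens[i]
        norm = self.k1 * (1.0 - self.b + self.b * self.doc_len[i] / self.avgdl)
        s = 0.0
        for term in query_terms:
            f = tf.get(term, 0)
            if f:
                s += self.idf(term) * f * (self.k1 + 1.0) / (f + norm)
        return s


class BM25Index:
    """Chunk index with per-source BM25 namespaces."""

    def __init__(self, chunks: Iterable[GuidelineChunk], k1: float = BM25_K1, b: float = BM25_B):
        self.chunks = sorted(chunks, key=lambda c: c.chunk_id)
        by_source: dict[Source, list[GuidelineChunk]] = {}
        for chunk in self.chunks:
            by_source.setdefault(chunk.source, []).append(chunk)
        self._namespaces = {s: _Namespace(cs, k1, b) for s, cs in by_source.items()}

    def sources(self) -> set[Source]:
        return set(self._namespaces)

    def retrieve(
        self,
        query: str,
        source_filter: Source,
        k: int = 6,
        min_score: float = 0.0,
    ) -> list[RetrievalResult]:
        """Top-k chunks of one guideline by BM25 relevance.

        Scores strictly below ``min_score`` are dropped; ties break on
        chunk_id so results are reproducible across runs.
        """
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        ns = self._namespaces.get(source_filter)
        if ns is None:
            raise ValueError(
                f"index holds no chunks for source {source_filter.value!r}"
            )
        terms = tokenize(query)
        scored = [(ns.score(terms, i), chunk) for i, chunk in enumerate(ns.chunks)]
        scored = [(s, c) for s, c in scored if s >= min_score]
        scored.sort(key=lambda sc: (-sc[0], sc[1].chunk_id))
        return [
            RetrievalResult(chunk=c, score=s, rank=r)
            for r, (s, c) in enumerate(scored[:k], start=1)
        ]


def retrieve(
    query: str,
    index: BM25Index,
    source_filter: Source,
    k: int = 6,
    min_score: float = 0.0,
) -> list[RetrievalResult]:
    """Functional wrapper around :meth:`BM25Index.retrieve`."""
    return index.retrieve(query, source_filter, k=k, min_score=min_score)
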
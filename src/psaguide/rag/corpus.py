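"""Guideline corpus loading and chunking.

The corpus is a directory of plain-text/markdown files with YAML
front-matter tagging each document with its guideline ``source`` (EAU or
AUA) and section. Paragraphs may open with one or more bracketed rule
identifiers (``[eau.psa_confirmatory_repeat] ...``) linking the passage to
the rule-engine rules it supports; the tags are stripped from the chunk
text and kept on the chunk, which is what makes the pipeline's
constrain-to-context audit possible.

Chunking is paragraph-aligned: paragraphs are packed greedily up to a
token budget with a token-bounded paragraph overlap between consecutive
chunks. Chunk ids are content hashes, so the same corpus always chunks to
the same ids.
"""
from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path
from typing import Iterable, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from ..engine import Source
from ..errors import ConfigurationError

logger = logging.getLogger(__name__)

_RULE_TAG = re.compile(r"^(?:\[[a-z0-9_.]+\]\s*)+", re.MULTILINE)
_TAG = re.compile(r"\[([a-z0-9_.]+)\]")


class CorpusDocument(BaseModel):
    model_config = ConfigDict(frozen=True)

    source: Source
    section: str = ""
    text: str

    @field_validator("source")
    @classmethod
    def _no_combined(cls, v: Source) -> Source:
        if v is Source.COMBINED:
            raise ValueError("corpus documents must be tagged EAU or AUA")
        return v


class ChunkConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    max_tokens: int = Field(default=300, ge=1)
    overlap: int = Field(default=50, ge=0)


class GuidelineChunk(BaseModel):
    model_config = ConfigDict(frozen=True)

    chunk_id: str
    source: Source
    section: str = ""
    text: str = Field(min_length=1)
    token_estimate: int = Field(ge=1)
    rule_ids: tuple[str, ...] = ()


def token_estimate(text: str) -> int:
    """Whitespace token count — the budget unit used throughout chunking."""
    return len(text.split())


def load_corpus(directory: str | Path) -> list[CorpusDocument]:
    """Load every ``.txt``/``.md`` file in *directory* as a tagged document.

    A file must carry ``source: EAU`` or ``source: AUA`` in its YAML
    front-matter; an untagged document is a configuration error.
    """
    directory = Path(directory)
    docs: list[CorpusDocument] = []
    for path in sorted(directory.glob("*")):
        if path.suffix.lower() not in {".txt", ".md"}:
            continue
        meta, body = _split_front_matter(path.read_text())
        if "source" not in meta:
            raise ConfigurationError(f"corpus document {path.name} has no source tag")
        try:
            docs.append(
                CorpusDocument(source=Source(meta["source"]), section=meta.get("section", ""), text=body)
            )
        except ValueError as exc:
            raise ConfigurationError(f"corpus document {path.name}: {exc}") from exc
    return docs


def _split_front_matter(text: str) -> tuple[dict, str]:
    if text.startswith("---"):
        parts = text.split("---", 2)
        if len(parts) == 3:
            meta = yaml.safe_load(parts[1]) or {}
            return dict(meta), parts[2].strip()
    return {}, text.strip()


def _paragraphs(text: str) -> list[tuple[str, tuple[str, ...]]]:
    """Split on blank lines; extract leading bracketed rule tags."""
    out = []
    for block in re.split(r"\n\s*\n", text):
        block = block.strip()
        if not block:
            continue
        m = _RULE_TAG.match(block)
        tags: tuple[str, ...] = ()
        if m:
            tags = tuple(_TAG.findall(m.group(0)))
            block = block[m.end():].strip()
        if block:
            out.append((" ".join(block.split()), tags))
    return out


def _make_chunk(source: Source, section: str, paras: list[tuple[str, tuple[str, ...]]]) -> GuidelineChunk:
    text = "\n\n".join(p for p, _ in paras)
    rule_ids = tuple(dict.fromkeys(t for _, tags in paras for t in tags))
    digest = hashlib.sha1(f"{source.value}|{text}".encode()).hexdigest()[:12]
    return GuidelineChunk(
        chunk_id=f"{source.value.lower()}-{digest}",
        source=source,
        section=section,
        text=text,
        token_estimate=token_estimate(text),
        rule_ids=rule_ids,
    )


def chunk_corpus(
    documents: Iterable[CorpusDocument],
    config: Optional[ChunkConfig] = None,
) -> list[GuidelineChunk]:
    """Split documents into paragraph-aligned chunks with stable ids."""
    config = config or ChunkConfig()
    chunks: list[GuidelineChunk] = []
    for doc in documents:
        paras = _paragraphs(doc.text)
        if not paras:
            logger.warning("corpus document (%s/%s) is empty; producing no chunks",
                           doc.source.value, doc.section)
            continue
        current: list[tuple[str, tuple[str, ...]]] = []
        used = 0
        for para in paras:
            n = token_estimate(para[0])
            if current and used + n > config.max_tokens:
                chunks.append(_make_chunk(doc.source, doc.section, current))
                # carry trailing paragraphs up to the overlap budget
                carry: list[tuple[str, tuple[str, ...]]] = []
                carried = 0
                for prev in reversed(current):
                    pn = token_estimate(prev[0])
                    if carried + pn > config.overlap:
                        break
                    carry.insert(0, prev)
                    carried += pn
                current, used = carry, carried
            current.append(para)
            used += n
        if current:
            chunks.append(_make_chunk(doc.source, doc.section, current))
    return chunks


def default_corpus_dir() -> Path:
    from importlib import resources

    return Path(str(resources.files("psaguide").joinpath("data", "corpus")))


def save_chunks(chunks: Iterable[GuidelineChunk], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chunk in chunks:
            fh.write(json.dumps(chunk.model_dump(mode="json"), sort_keys=True) + "\n")


def load_chunks(path: str | Path) -> list[GuidelineChunk]:
    chunks = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chunks.append(GuidelineChunk.model_validate(json.loads(line)))
    return chunks
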
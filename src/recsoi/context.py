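"""Paragraph context and highlight extraction for recommended SOIs.

A recommended SOI is a single sentence; readers usually need its
surrounding paragraph to judge relevance.  Two highlight strategies are
implemented on top of the extracted paragraph:

* ``previous_sentence`` — naively highlight the sentence immediately before
  the SOI (empty when the SOI opens its paragraph);
* ``llm`` — ask a language model, via a pluggable adapter, for the most
  relevant passage(s), then keep only outputs that are verbatim substrings
  of the paragraph and not the SOI itself.  The strict validation guards
  against the two classic LLM failure modes: silently modified text and
  extraneous added material.

An offline, deterministic mock adapter (highest token overlap with the SOI)
makes the full pipeline testable without network access.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Protocol

from .corpus import PaperDoc, SentenceUnit, SOIRecord
from .errors import IntegrityError

__all__ = [
    "ParagraphContext",
    "HighlightSet",
    "LLMAdapter",
    "MockOverlapAdapter",
    "extract_paragraph",
    "highlight_previous_sentence",
    "render_prompt",
    "validate_llm_passages",
    "prompt_template",
]

STRATEGIES = ("none", "previous_sentence", "llm")


@dataclass
class ParagraphContext:
    """The sentences sharing the SOI's paragraph, with the SOI's position."""

    paper_id: str
    paragraph_index: int
    sentences: list[SentenceUnit]
    soi_position: int

    def __post_init__(self):
        if not 0 <= self.soi_position < len(self.sentences):
            raise IntegrityError("soi_position out of range")
        if any(s.paragraph_index != self.paragraph_index for s in self.sentences):
            raise IntegrityError("all sentences must share paragraph_index")

    @property
    def soi_text(self) -> str:
        return self.sentences[self.soi_position].text

    @property
    def text(self) -> str:
        """Canonical paragraph text: sentences joined with single spaces."""
        return " ".join(s.text for s in self.sentences)


@dataclass
class HighlightSet:
    """Validated highlight passages for one paragraph context.

    Every passage is a verbatim substring of the paragraph text and never
    equals the SOI itself.  ``dropped`` records rejected candidates with the
    failure reason (modified-text | is-soi | extraneous).
    """

    strategy: str
    passages: list[str] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def spans(self, paragraph: str) -> list[tuple[int, int]]:
        """Resolve each passage to its first character span in the paragraph."""
        out = []
        for p in self.passages:
            start = paragraph.find(p)
            if start < 0:
                raise IntegrityError(f"passage not found in paragraph: {p!r}")
            out.append((start, start + len(p)))
        return out


class LLMAdapter(Protocol):
    """Contract for passage-extraction language models."""

    name: str
    deterministic: bool

    def complete(self, prompt: str) -> str: ...


def extract_paragraph(paper: PaperDoc, soi: SOIRecord) -> ParagraphContext:
    """Collect the sentences sharing the SOI's paragraph, in order."""
    if soi.paper_id != paper.paper_id:
        raise IntegrityError(
            f"soi {soi.soi_id} belongs to paper {soi.paper_id}, not "
            f"{paper.paper_id}"
        )
    target = (soi.sentence.paragraph_index, soi.sentence.sentence_index)
    para = [
        s for s in paper.sentences if s.paragraph_index == soi.sentence.paragraph_index
    ]
    positions = [
        i
        for i, s in enumerate(para)
        if (s.paragraph_index, s.sentence_index) == target
    ]
    if not positions:
        raise IntegrityError(
            f"soi {soi.soi_id} not found in paper {paper.paper_id}"
        )
    return ParagraphContext(
        paper_id=paper.paper_id,
        paragraph_index=soi.sentence.paragraph_index,
        sentences=para,
        soi_position=positions[0],
    )


def highlight_previous_sentence(ctx: ParagraphContext) -> HighlightSet:
    """Highlight the single sentence before the SOI (possibly none)."""
    if ctx.soi_position == 0:
        return HighlightSet(strategy="previous_sentence", passages=[])
    return HighlightSet(
        strategy="previous_sentence",
        passages=[ctx.sentences[ctx.soi_position - 1].text],
    )


def prompt_template() -> str:
    """The passage-extraction prompt template (versioned text asset)."""
    return (
        resources.files("recsoi")
        .joinpath("assets/gpt_prompt.txt")
        .read_text(encoding="utf-8")
    )


def render_prompt(ctx: ParagraphContext) -> str:
    """Substitute paragraph and SOI into the prompt template.

    The SOI placeholder occurs twice (once to name the statement, once in
    the exclusion clause); both are substituted.
    """
    return (
        prompt_template()
        .replace("{PARAGRAPH}", ctx.text)
        .replace("{STATEMENT OF IGNORANCE}", ctx.soi_text)
    )


_QUOTES = "\"'“”‘’"


def _split_output(raw: str) -> list[str]:
    """Split an LLM response into candidate passages.

    One candidate per non-empty line, with surrounding straight/curly quotes
    stripped.
    """
    out = []
    for line in raw.splitlines():
        cand = line.strip().strip(_QUOTES).strip()
        if cand:
            out.append(cand)
    return out


def validate_llm_passages(ctx: ParagraphContext, raw_output: str) -> HighlightSet:
    """Keep only verbatim, non-SOI passages from an LLM response.

    Rejected candidates are annotated: ``is-soi`` (equals the SOI text),
    ``modified-text`` (overlaps the paragraph's vocabulary but is not a
    verbatim substring), ``extraneous`` (shares no token with the
    paragraph).  Idempotent: validating the joined kept passages changes
    nothing.  An empty validated set is a legal outcome.
    """
    paragraph = ctx.text
    para_tokens = set(paragraph.lower().split())
    kept: list[str] = []
    dropped: list[tuple[str, str]] = []
    for cand in _split_output(raw_output):
        if cand == ctx.soi_text:
            dropped.append((cand, "is-soi"))
        elif cand in paragraph:
            if cand not in kept:
                kept.append(cand)
        elif set(cand.lower().split()) & para_tokens:
            dropped.append((cand, "modified-text"))
        else:
            dropped.append((cand, "extraneous"))
    return HighlightSet(strategy="llm", passages=kept, dropped=dropped)


@dataclass
class MockOverlapAdapter:
    """Offline stand-in adapter (synthetic): returns the non-SOI context
    sentence with the highest token overlap with the SOI.

    Deterministic, so the llm strategy is exercisable in tests and studies
    without any network model.  Requires the rendered prompt produced by
    :func:`render_prompt` only for interface compatibility; selection uses
    the context passed at construction.
    """

    ctx: ParagraphContext
    name: str = "mock-overlap"
    deterministic: bool = True

    def complete(self, prompt: str) -> str:
        soi_tokens = set(self.ctx.soi_text.lower().split())
        best, best_score = "", -1
        for i, s in enumerate(self.ctx.sentences):
            if i == self.ctx.soi_position:
                continue
            score = len(soi_tokens & set(s.text.lower().split()))
            if score > best_score:
                best, best_score = s.text, score
        return best
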
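"""Corpus domain model: authors, papers, prior abstracts and their SOIs.

A corpus bundles four record kinds.  ``PaperDoc`` objects are the documents
from which statements of ignorance (SOIs) are mined; ``AbstractDoc`` objects
are an author's *prior* first-author abstracts, used only to build their
profile.  The separation mirrors the temporal protocol of the recommendation
experiment: profiles are learned from text strictly preceding the papers
whose SOIs are candidates for recommendation.

Serialization is line-delimited JSON (JSONL), one object per line with a
``kind`` discriminator in {author, paper, abstract, soi}.  All text is NFC
normalized on load so that verbatim-substring checks downstream are stable.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import numpy as np

from .categories import RECOMMENDABLE_CATEGORIES, normalize_category
from .errors import (
    ColdStartError,
    ConfigurationError,
    CorpusParseError,
    IntegrityError,
)

__all__ = [
    "AuthorRef",
    "SentenceUnit",
    "PaperDoc",
    "AbstractDoc",
    "SOIRecord",
    "Corpus",
    "load_corpus",
    "write_corpus",
    "filter_recommendable_sois",
    "select_profile_abstracts",
    "temporal_split_check",
]


def _nfc(s: str) -> str:
    return unicodedata.normalize("NFC", s)


@dataclass(frozen=True)
class AuthorRef:
    """A researcher, identified by an opaque unique id."""

    author_id: str
    display_name: str = ""

    def __post_init__(self):
        if not self.author_id:
            raise IntegrityError("author_id must be non-empty")


@dataclass(frozen=True)
class SentenceUnit:
    """One pre-segmented sentence of a paper or abstract.

    ``is_soi`` marks statements of ignorance; if so, ``soi_category`` holds
    one of the 13 ignorance categories.  ``concepts`` carries optional named
    entities found in the sentence (used by the concepts heuristic).
    """

    text: str
    paragraph_index: int
    sentence_index: int
    is_soi: bool = False
    soi_category: str | None = None
    concepts: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.text:
            raise IntegrityError("sentence text must be non-empty")
        if self.paragraph_index < 0 or self.sentence_index < 0:
            raise IntegrityError("sentence/paragraph indices must be non-negative")
        if self.soi_category is not None and not self.is_soi:
            raise IntegrityError(
                "soi_category present on a sentence with is_soi=False"
            )


@dataclass(frozen=True)
class PaperDoc:
    """A full paper: source of SOI candidates.

    ``time_rank`` is an integer publication-order surrogate, comparable with
    the ``time_rank`` of abstracts; only the strict "prior to" relation is
    ever used.
    """

    paper_id: str
    first_author: str
    co_authors: tuple[str, ...] = ()
    sentences: tuple[SentenceUnit, ...] = ()
    time_rank: int | None = None

    def __post_init__(self):
        if self.first_author in self.co_authors:
            raise IntegrityError(
                f"paper {self.paper_id}: first_author appears in co_authors"
            )
        keys = [(s.paragraph_index, s.sentence_index) for s in self.sentences]
        if sorted(keys) != keys or len(set(keys)) != len(keys):
            raise IntegrityError(
                f"paper {self.paper_id}: sentence indices must be strictly increasing"
            )


@dataclass(frozen=True)
class AbstractDoc:
    """A prior first-author abstract of one researcher."""

    abstract_id: str
    author_id: str
    sentences: tuple[SentenceUnit, ...]
    time_rank: int

    def __post_init__(self):
        if len(self.sentences) == 0:
            raise IntegrityError(f"abstract {self.abstract_id}: needs >= 1 sentence")

    @property
    def text(self) -> str:
        return " ".join(s.text for s in self.sentences)


@dataclass(frozen=True)
class SOIRecord:
    """One labeled statement of ignorance, anchored in its source paper."""

    soi_id: str
    paper_id: str
    sentence: SentenceUnit
    category: str
    concepts: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.sentence.is_soi:
            raise IntegrityError(f"soi {self.soi_id}: sentence.is_soi must be True")
        if self.sentence.soi_category != self.category:
            raise IntegrityError(
                f"soi {self.soi_id}: category differs from sentence.soi_category"
            )

    @property
    def text(self) -> str:
        return self.sentence.text


@dataclass
class Corpus:
    authors: list[AuthorRef] = field(default_factory=list)
    papers: list[PaperDoc] = field(default_factory=list)
    abstracts: list[AbstractDoc] = field(default_factory=list)
    sois: list[SOIRecord] = field(default_factory=list)

    # -- lookups -----------------------------------------------------------
    def paper(self, paper_id: str) -> PaperDoc:
        try:
            return self._paper_index[paper_id]
        except KeyError:
            raise IntegrityError(f"unknown paper_id: {paper_id}") from None

    def abstracts_of(self, author_id: str) -> list[AbstractDoc]:
        return [a for a in self.abstracts if a.author_id == author_id]

    def papers_of(self, author_id: str) -> list[PaperDoc]:
        return [p for p in self.papers if p.first_author == author_id]

    @property
    def _paper_index(self) -> dict[str, PaperDoc]:
        return {p.paper_id: p for p in self.papers}

    def validate(self) -> None:
        """Enforce referential integrity; raise IntegrityError on violation."""
        author_ids = [a.author_id for a in self.authors]
        if len(set(author_ids)) != len(author_ids):
            dupes = {x for x in author_ids if author_ids.count(x) > 1}
            raise IntegrityError(f"duplicate author_id(s): {sorted(dupes)}")
        known_authors = set(author_ids)
        paper_ids = [p.paper_id for p in self.papers]
        if len(set(paper_ids)) != len(paper_ids):
            raise IntegrityError("duplicate paper_id(s)")
        known_papers = set(paper_ids)
        for p in self.papers:
            for aid in (p.first_author, *p.co_authors):
                if aid not in known_authors:
                    raise IntegrityError(
                        f"paper {p.paper_id} references unknown author {aid!r}"
                    )
        abstract_ids = [a.abstract_id for a in self.abstracts]
        if len(set(abstract_ids)) != len(abstract_ids):
            raise IntegrityError("duplicate abstract_id(s)")
        for a in self.abstracts:
            if a.author_id not in known_authors:
                raise IntegrityError(
                    f"abstract {a.abstract_id} references unknown author "
                    f"{a.author_id!r}"
                )
        soi_ids = [s.soi_id for s in self.sois]
        if len(set(soi_ids)) != len(soi_ids):
            raise IntegrityError("duplicate soi_id(s)")
        for s in self.sois:
            if s.paper_id not in known_papers:
                raise IntegrityError(
                    f"soi {s.soi_id} references unknown paper {s.paper_id!r}"
                )


# ---------------------------------------------------------------------------
# JSONL I/O
# ---------------------------------------------------------------------------


def _sentence_from_json(obj: dict) -> SentenceUnit:
    cat = obj.get("soi_category")
    return SentenceUnit(
        text=_nfc(obj["text"]),
        paragraph_index=int(obj["paragraph_index"]),
        sentence_index=int(obj["sentence_index"]),
        is_soi=bool(obj.get("is_soi", False)),
        soi_category=normalize_category(cat) if cat is not None else None,
        concepts=frozenset(_nfc(c).lower() for c in obj.get("concepts", [])),
    )


def _sentence_to_json(s: SentenceUnit) -> dict:
    out: dict = {
        "text": s.text,
        "paragraph_index": s.paragraph_index,
        "sentence_index": s.sentence_index,
        "is_soi": s.is_soi,
    }
    if s.soi_category is not None:
        out["soi_category"] = s.soi_category
    if s.concepts:
        out["concepts"] = sorted(s.concepts)
    return out


def load_corpus(path: str | Path) -> Corpus:
    """Load and fully validate a JSONL corpus.

    Raises :class:`CorpusParseError` (with the offending line number) for
    malformed lines and :class:`IntegrityError` for dangling references.
    """
    path = Path(path)
    corpus = Corpus()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(lineno, f"invalid JSON ({exc.msg})") from exc
            try:
                kind = obj["kind"]
                if kind == "author":
                    corpus.authors.append(
                        AuthorRef(obj["author_id"], _nfc(obj.get("display_name", "")))
                    )
                elif kind == "paper":
                    corpus.papers.append(
                        PaperDoc(
                            paper_id=obj["paper_id"],
                            first_author=obj["first_author"],
                            co_authors=tuple(obj.get("co_authors", [])),
                            sentences=tuple(
                                _sentence_from_json(s) for s in obj["sentences"]
                            ),
                            time_rank=obj.get("time_rank"),
                        )
                    )
                elif kind == "abstract":
                    corpus.abstracts.append(
                        AbstractDoc(
                            abstract_id=obj["abstract_id"],
                            author_id=obj["author_id"],
                            sentences=tuple(
                                _sentence_from_json(s) for s in obj["sentences"]
                            ),
                            time_rank=int(obj["time_rank"]),
                        )
                    )
                elif kind == "soi":
                    corpus.sois.append(
                        SOIRecord(
                            soi_id=obj["soi_id"],
                            paper_id=obj["paper_id"],
                            sentence=_sentence_from_json(obj["sentence"]),
                            category=normalize_category(obj["category"]),
                            concepts=frozenset(
                                _nfc(c).lower() for c in obj.get("concepts", [])
                            ),
                        )
                    )
                else:
                    raise CorpusParseError(lineno, f"unknown kind {kind!r}")
            except CorpusParseError:
                raise
            except KeyError as exc:
                raise CorpusParseError(lineno, f"missing field {exc}") from exc
            except (TypeError, ValueError) as exc:
                raise CorpusParseError(lineno, str(exc)) from exc
    corpus.validate()
    return corpus


def write_corpus(corpus: Corpus, path_or_file: str | Path | IO[str]) -> None:
    """Write a corpus in canonical JSONL form.

    Canonical means: record order authors, papers, abstracts, sois (input
    order preserved within each kind), sorted JSON keys, compact separators.
    ``load_corpus`` then ``write_corpus`` is a byte-level fixed point.
    """

    def _dump(fh: IO[str]) -> None:
        def emit(obj: dict) -> None:
            fh.write(json.dumps(obj, sort_keys=True, ensure_ascii=False,
                                separators=(",", ":")))
            fh.write("\n")

        for a in corpus.authors:
            emit({"kind": "author", "author_id": a.author_id,
                  "display_name": a.display_name})
        for p in corpus.papers:
            obj: dict = {
                "kind": "paper",
                "paper_id": p.paper_id,
                "first_author": p.first_author,
                "co_authors": list(p.co_authors),
                "sentences": [_sentence_to_json(s) for s in p.sentences],
            }
            if p.time_rank is not None:
                obj["time_rank"] = p.time_rank
            emit(obj)
        for ab in corpus.abstracts:
            emit({
                "kind": "abstract",
                "abstract_id": ab.abstract_id,
                "author_id": ab.author_id,
                "sentences": [_sentence_to_json(s) for s in ab.sentences],
                "time_rank": ab.time_rank,
            })
        for s in corpus.sois:
            obj = {
                "kind": "soi",
                "soi_id": s.soi_id,
                "paper_id": s.paper_id,
                "sentence": _sentence_to_json(s.sentence),
                "category": s.category,
            }
            if s.concepts:
                obj["concepts"] = sorted(s.concepts)
            emit(obj)

    if hasattr(path_or_file, "write"):
        _dump(path_or_file)  # type: ignore[arg-type]
    else:
        with Path(path_or_file).open("w", encoding="utf-8") as fh:
            _dump(fh)


# ---------------------------------------------------------------------------
# Selection and checks
# ---------------------------------------------------------------------------


def filter_recommendable_sois(corpus: Corpus) -> list[SOIRecord]:
    """Keep only SOIs whose category signals a pursuable research direction.

    The recommendable subset is {full unknown, explicit question,
    problem or complication, future work, future prediction}; order of the
    input is preserved.
    """
    return [s for s in corpus.sois if s.category in RECOMMENDABLE_CATEGORIES]


def select_profile_abstracts(
    corpus: Corpus, author: str, cap: int = 5, seed: int = 0
) -> list[AbstractDoc]:
    """Pick the (at most ``cap``) abstracts used to build an author profile.

    When an author has more than ``cap`` prior abstracts, ``cap`` of them are
    drawn uniformly at random without replacement (reproducibly under
    ``seed``); the experiment caps profiles at 5 abstracts to model junior
    researchers.  Returned abstracts keep their corpus order.
    """
    if cap <= 0:
        raise ConfigurationError("cap must be positive")
    available = corpus.abstracts_of(author)
    if not available:
        raise ColdStartError(
            f"author {author!r} has no prior abstracts; supply a proxy author"
        )
    if len(available) <= cap:
        return available
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(available), size=cap, replace=False)
    return [available[i] for i in sorted(idx)]


def temporal_split_check(
    corpus: Corpus,
) -> list[tuple[str, str, str]]:
    """List (author, abstract, paper) triples violating the temporal split.

    Every profile abstract must strictly precede the author's oldest paper in
    the SOI corpus.  An empty list certifies the split.  Authors without
    papers (or without abstracts) impose no constraint.
    """
    violations: list[tuple[str, str, str]] = []
    for author in corpus.authors:
        papers = corpus.papers_of(author.author_id)
        abstracts = corpus.abstracts_of(author.author_id)
        if not papers or not abstracts:
            continue
        if any(p.time_rank is None for p in papers):
            missing = [p.paper_id for p in papers if p.time_rank is None]
            raise ConfigurationError(
                f"papers missing time_rank for author {author.author_id!r}: "
                f"{missing}"
            )
        oldest = min(papers, key=lambda p: p.time_rank)  # type: ignore[arg-type,return-value]
        for ab in abstracts:
            if not ab.time_rank < oldest.time_rank:  # strict "prior to"
                violations.append(
                    (author.author_id, ab.abstract_id, oldest.paper_id)
                )
    return violations
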
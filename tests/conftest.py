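"""Shared fixtures: a tiny handcrafted corpus and small simulated corpora."""

from __future__ import annotations

import pytest

from recsoi.corpus import (
    AbstractDoc,
    AuthorRef,
    Corpus,
    PaperDoc,
    SentenceUnit,
    SOIRecord,
)
from recsoi.simulate import SimConfig, simulate_corpus
from recsoi.study import COMBINATIONS, Judgment, JudgmentTable


def _sent(text, p, i, soi=None, concepts=()):
    return SentenceUnit(
        text=text,
        paragraph_index=p,
        sentence_index=i,
        is_soi=soi is not None,
        soi_category=soi,
        concepts=frozenset(concepts),
    )


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Two-topic, three-author corpus with known relevance structure.

    alice works on zebrafish heart regeneration (bob co-authors her paper);
    bob on cardiac fibrosis; carol has an abstract but no paper.
    """
    authors = [
        AuthorRef("alice", "Alice A"),
        AuthorRef("bob", "Bob B"),
        AuthorRef("carol", "Carol C"),
    ]
    abstracts = [
        AbstractDoc(
            "alice-a1",
            "alice",
            (
                _sent("zebrafish heart regeneration depends on cardiomyocyte "
                      "dedifferentiation", 0, 0, concepts=("zebrafish", "heart")),
                _sent("we imaged regenerating zebrafish ventricles over time",
                      0, 1, concepts=("zebrafish",)),
            ),
            time_rank=0,
        ),
        AbstractDoc(
            "alice-a2",
            "alice",
            (
                _sent("cardiomyocyte proliferation drives zebrafish cardiac "
                      "repair", 0, 0, concepts=("zebrafish", "cardiomyocyte")),
            ),
            time_rank=1,
        ),
        AbstractDoc(
            "bob-a1",
            "bob",
            (
                _sent("cardiac fibrosis limits mammalian heart repair", 0, 0,
                      concepts=("fibrosis", "heart")),
                _sent("fibroblast activation markers were profiled", 0, 1,
                      concepts=("fibroblast",)),
            ),
            time_rank=0,
        ),
        AbstractDoc(
            "carol-a1",
            "carol",
            (_sent("folate intake during gestation was surveyed", 0, 0,
                   concepts=("folate",)),),
            time_rank=0,
        ),
    ]
    p_alice_sents = (
        _sent("zebrafish regenerate myocardium after injury", 0, 0,
              concepts=("zebrafish",)),
        _sent("the signals gating cardiomyocyte dedifferentiation remain "
              "unknown", 0, 1, soi="full unknown",
              concepts=("cardiomyocyte",)),
        _sent("future work should map zebrafish regeneration enhancers", 0, 2,
              soi="future work", concepts=("zebrafish",)),
        _sent("this question is answered by our lineage tracing", 1, 0,
              soi="question answered by this work"),
    )
    p_bob_sents = (
        _sent("fibrosis outcome varies across species", 0, 0,
              concepts=("fibrosis",)),
        _sent("whether fibroblast reprogramming is feasible in vivo is an "
              "open question", 0, 1, soi="explicit question",
              concepts=("fibroblast",)),
    )
    papers = [
        PaperDoc("p-alice", "alice", ("bob",), p_alice_sents, time_rank=100),
        PaperDoc("p-bob", "bob", (), p_bob_sents, time_rank=101),
    ]
    sois = [
        SOIRecord("soi-1", "p-alice", p_alice_sents[1], "full unknown",
                  frozenset({"cardiomyocyte"})),
        SOIRecord("soi-2", "p-alice", p_alice_sents[2], "future work",
                  frozenset({"zebrafish"})),
        SOIRecord("soi-3", "p-alice", p_alice_sents[3],
                  "question answered by this work"),
        SOIRecord("soi-4", "p-bob", p_bob_sents[1], "explicit question",
                  frozenset({"fibroblast"})),
    ]
    corpus = Corpus(authors=authors, papers=papers, abstracts=abstracts,
                    sois=sois)
    corpus.validate()
    return corpus


@pytest.fixture(scope="session")
def small_sim():
    """10-author simulated corpus used by cross-module checks."""
    return simulate_corpus(SimConfig(n_authors=10, n_topics=2, seed=7))


def table_from_combination_counts(
    counts: dict[str, int], participant: str = "P"
) -> JudgmentTable:
    """Build a complete judgment table realizing given combination counts."""
    truth_of = {name: key for key, name in COMBINATIONS.items()}
    judgments = []
    soi_no = 0
    for name, n in counts.items():
        llm, ps, para = truth_of[name]
        for _ in range(n):
            sid = f"s{soi_no:02d}"
            soi_no += 1
            judgments.extend(
                [
                    Judgment(participant, sid, "llm", llm),
                    Judgment(participant, sid, "previous_sentence", ps),
                    Judgment(participant, sid, "none", para),
                ]
            )
    return JudgmentTable(judgments)
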